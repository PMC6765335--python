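# Delay-model fitted parameters, nfg pre group.
S_i: 0.00012
S_g: 0.013
hepatic_input: 2.16
d_i: 0.8
sigma1: 12.434
sigma2: 0.2
alpha: 150
sigma: 150
gamma: 3.18
beta: 4.6
g0: 0.65
g1: 28.85
I2: 31.1
kappa: 3.2
d_f: 0.08
tau: 3.8
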