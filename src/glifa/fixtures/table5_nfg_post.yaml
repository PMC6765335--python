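# Delay-model fitted parameters, nfg post group.
S_i: 2.5e-06
S_g: 0.04
hepatic_input: 2.16
d_i: 0.3
sigma1: 12.434
sigma2: 0.5
alpha: 165
sigma: 150
gamma: 3.5
beta: 4.6
g0: 10.5
g1: 35.5
I2: 20.1
kappa: 10.5
d_f: 0.08
tau: 1.2
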