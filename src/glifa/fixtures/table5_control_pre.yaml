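# Delay-model fitted parameters, control pre group.
S_i: 1.06e-07
S_g: 0.04
hepatic_input: 2.16
d_i: 0.072
sigma1: 10.434
sigma2: 0.1
alpha: 250
sigma: 650
gamma: 1.45
beta: 4.6
g0: 2.5
g1: 30.5
I2: 10.5
kappa: 2.68
d_f: 5.8
tau: 8.25
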