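# Delay-model fitted parameters, t2dm post group.
S_i: 4.06e-05
S_g: 0.0236
hepatic_input: 2.16
d_i: 0.12
sigma1: 12.434
sigma2: 0.09
alpha: 150
sigma: 150
gamma: 2.45
beta: 4.6
g0: 0.5
g1: 18.85
I2: 24.1025
kappa: 3.68
d_f: 0.08
tau: 8.25
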