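# Delay-model fitted parameters, t2dm pre group.
S_i: 5.06e-06
S_g: 0.022
hepatic_input: 3.15
d_i: 0.1
sigma1: 25.11
sigma2: 1.093
alpha: 215
sigma: 150
gamma: 4.5
beta: 12.6
g0: 1.5
g1: 24
I2: 30.5
kappa: 2.8
d_f: 0.08
tau: 6.25
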