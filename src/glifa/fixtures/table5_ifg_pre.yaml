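# Delay-model fitted parameters, ifg pre group.
S_i: 0.00018
S_g: 0.01
hepatic_input: 4.16
d_i: 0.4
sigma1: 20.11
sigma2: 0.001
alpha: 119
sigma: 150
gamma: 3.4
beta: 12.6
g0: 1.5
g1: 30.85
I2: 33.025
kappa: 6.2
d_f: 0.08
tau: 15.24
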