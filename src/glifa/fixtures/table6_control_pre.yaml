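# Minimal-model fitted parameters, control pre group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.042
S_I: 2.07e-05
c_X: 3.5
l0: 0.95
l2: 12.85
X2: 4.25
A: 4.2
c_f: 0.0295
G_b: 53.99797237
I_b: 14.16985483
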