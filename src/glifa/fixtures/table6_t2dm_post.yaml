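# Minimal-model fitted parameters, t2dm post group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.023
S_I: 1.07e-07
c_X: 0.12
l0: 34.2
l2: 60.5
X2: 14.2
A: 6.5
c_f: 0.15
G_b: 88.12230033
I_b: 22.44800969
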