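# Minimal-model fitted parameters, t2dm pre group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.023
S_I: 5.07e-06
c_X: 0.105
l0: 40.2
l2: 34.85
X2: 12.25
A: 3.5
c_f: 0.09
G_b: 142.0084943
I_b: 35.92326189
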