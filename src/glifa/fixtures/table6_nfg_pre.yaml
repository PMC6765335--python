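# Minimal-model fitted parameters, nfg pre group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.04
S_I: 7e-07
c_X: 0.08
l0: 5.2
l2: 16.85
X2: 20.25
A: 3.5
c_f: 0.038
G_b: 154.2479555
I_b: 8.361892522
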