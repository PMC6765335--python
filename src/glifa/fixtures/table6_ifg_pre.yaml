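# Minimal-model fitted parameters, ifg pre group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.03
S_I: 5.07e-05
c_X: 2.1
l0: 20.2
l2: 46.85
X2: 41.25
A: 2.5
c_f: 0.12
G_b: 228.9836696
I_b: 45.37352447
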