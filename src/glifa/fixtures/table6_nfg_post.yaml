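# Minimal-model fitted parameters, nfg post group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.09
S_I: 5.07e-05
c_X: 0.25
l0: 10.02
l2: 33.5
X2: 5.2
A: 3.5
c_f: 0.065
G_b: 53.99163941
I_b: 2.477594563
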