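# Minimal-model fitted parameters, ifg post group.
# G_b and I_b are not part of the fitted set; for synthetic runs they
# are set to the basal state of the paired delay-model parameter set.
S_G: 0.038
S_I: 5.07e-06
c_X: 0.075
l0: 16.2
l2: 44.5
X2: 4.2
A: 2.5
c_f: 0.099
G_b: 68.08566242
I_b: 5.535490434
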