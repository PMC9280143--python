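# Phase-recovery study: two-stage gambling design, groups of 200 subjects
paradigm: gambling
p_ref_given_pos: 0.69
p_ref_given_neg: 0.57
p_cond_pos: 0.5
n_subjects: 200
n_replicates: 500
seed: 42
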