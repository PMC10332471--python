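cov_margin=10
emit_highlight=False
emit_mask=False
emit_metrics=False
lam=1.2
max_iter=100
mu0=0.0006
output_dir='.'
s_hard=0.3
se_size=7
v_hard=0.7
zeta_rel=0.0001
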