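name	notation	family
ntn_hydrolase_core	NCSGKHxAM	PF06089.11
dgcgapl_block	DGCGAPL	PF06089.11
shsge_helix	SHSGEx(2)H	PF06089.11
prs_kp_helix	PRSx(2)KPxQ	PF06089.11
site_b_shtgq	SHTGQxHFV	PF06089.11
thr_loop_ggtia	GGTIA	PF00710.11
catalytic_hgtdt	HGTDT	PF00710.11
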