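label	hemisphere	lobe_group	brodmann_label	processes
A10l_l	LEFT	FRO	BA10	PLANNING
A10m_l	LEFT	FRO	BA10	PLANNING
A11l_l	LEFT	FRO	BA11	MOTIVATION
A11m_l	LEFT	FRO	BA11	MOTIVATION
A4hf_l	LEFT	FRO	BA4	EXECUTION
A4ll_l	LEFT	FRO	BA4	EXECUTION
A4t_l	LEFT	FRO	BA4	EXECUTION
A4tl_l	LEFT	FRO	BA4	EXECUTION
A4ul_l	LEFT	FRO	BA4	EXECUTION
A6cdl_l	LEFT	FRO	BA6	PLANNING;TIMING
A6cvl_l	LEFT	FRO	BA6	PLANNING;TIMING
A6dl_l	LEFT	FRO	BA6	PLANNING;TIMING
A6m_l	LEFT	FRO	BA6	PLANNING;TIMING
A6vl_l	LEFT	FRO	BA6	PLANNING;TIMING
A9/46d_l	LEFT	FRO	BA9/46	TIMING
A9l_l	LEFT	FRO	BA9	PLANNING;TIMING
A9m_l	LEFT	FRO	BA9	DECISION;PLANNING
A10l_r	RIGHT	FRO	BA10	PLANNING
A10m_r	RIGHT	FRO	BA10	PLANNING
A11l_r	RIGHT	FRO	BA11	MOTIVATION
A11m_r	RIGHT	FRO	BA11	MOTIVATION
A4hf_r	RIGHT	FRO	BA4	EXECUTION
A4ll_r	RIGHT	FRO	BA4	EXECUTION
A4t_r	RIGHT	FRO	BA4	EXECUTION
A4tl_r	RIGHT	FRO	BA4	EXECUTION
A4ul_r	RIGHT	FRO	BA4	EXECUTION
A6cdl_r	RIGHT	FRO	BA6	PLANNING;TIMING
A6cvl_r	RIGHT	FRO	BA6	PLANNING;TIMING
A6dl_r	RIGHT	FRO	BA6	PLANNING;TIMING
A6m_r	RIGHT	FRO	BA6	PLANNING;TIMING
A6vl_r	RIGHT	FRO	BA6	PLANNING;TIMING
A9/46d_r	RIGHT	FRO	BA9/46	TIMING
A9l_r	RIGHT	FRO	BA9	PLANNING;TIMING
A9m_r	RIGHT	FRO	BA9	DECISION;PLANNING
G_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
dId_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
dIg_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
dla_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
vId/vIg_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
vla_l	LEFT	INS	BA13/14/16	AGENCY;MOTIVATION
G_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
dId_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
dIg_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
dla_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
vId/vIg_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
vla_r	RIGHT	INS	BA13/14/16	AGENCY;MOTIVATION
A23c_l	LEFT	LIM	BA23	MOD_MOTIVATION
A23d_l	LEFT	LIM	BA23	MOD_MOTIVATION
A23v_l	LEFT	LIM	BA23	MOD_MOTIVATION
A24cd_l	LEFT	LIM	BA24	PLANNING
A24rv_l	LEFT	LIM	BA24	PLANNING
A31_l	LEFT	LIM	BA31	MOD_MOTIVATION
A32p_l	LEFT	LIM	BA32	PLANNING
A32sg_l	LEFT	LIM	BA32	PLANNING
A23c_r	RIGHT	LIM	BA23	MOD_MOTIVATION
A23d_r	RIGHT	LIM	BA23	MOD_MOTIVATION
A23v_r	RIGHT	LIM	BA23	MOD_MOTIVATION
A24cd_r	RIGHT	LIM	BA24	PLANNING
A24rv_r	RIGHT	LIM	BA24	PLANNING
A31_r	RIGHT	LIM	BA31	MOD_MOTIVATION
A32p_r	RIGHT	LIM	BA32	PLANNING
A32sg_r	RIGHT	LIM	BA32	PLANNING
cpSTS_l	LEFT	TEM	BA22	MOD_AGENCY
cpSTS_r	RIGHT	TEM	BA22	MOD_AGENCY
A39c_l	LEFT	PAR	BA39	MOD_AGENCY
A39rd_l	LEFT	PAR	BA39	MOD_AGENCY
A39rv_l	LEFT	PAR	BA39	MOD_AGENCY
A40rd_l	LEFT	PAR	BA40	PLANNING
A40rv_l	LEFT	PAR	BA40	PLANNING
A39c_r	RIGHT	PAR	BA39	MOD_AGENCY
A39rd_r	RIGHT	PAR	BA39	MOD_AGENCY
A39rv_r	RIGHT	PAR	BA39	MOD_AGENCY
A40rd_r	RIGHT	PAR	BA40	PLANNING
A40rv_r	RIGHT	PAR	BA40	PLANNING
V5_MT_plus_l	LEFT	OCC	BA19	MOD_AGENCY
V5_MT_plus_r	RIGHT	OCC	BA19	MOD_AGENCY
NAC_l	LEFT	SCN	N/A	MOTIVATION
lAmyg_l	LEFT	SCN	N/A	MOTIVATION
mAmyg_l	LEFT	SCN	N/A	MOTIVATION
NAC_r	RIGHT	SCN	N/A	MOTIVATION
lAmyg_r	RIGHT	SCN	N/A	MOTIVATION
mAmyg_r	RIGHT	SCN	N/A	MOTIVATION
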