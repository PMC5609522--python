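# Sugar beet aquaporin catalog: one row per annotated protein/transcript.
# transcript_tag distinguishes transcripts of a single gene (ASCII for Greek).
family	gene	transcript_tag	gene_id	length	MW	pI	TMH
PIP	BvPIP1;1		Bv1g004510_fpur.t1	289	31.1	8.84	5
PIP	BvPIP1;2		Bv1g004520_shpz.t1	285	30.67	9.05	6
PIP	BvPIP1;3		Bv2g024120_gqok.t1	286	30.74	9.14	6
PIP	BvPIP2;1		Bv7g163390_cqnr.t1	284	30.32	8.31	6
PIP	BvPIP2;2		Bv9g210030_ixem.t1	288	31.09	7.08	6
PIP	BvPIP2;3		Bv9g210020_yige.t1	274	29.64	8.97	6
PIP	BvPIP2;4		Bv9g216070_reke.t1	281	30.13	8.84	6
TIP	BvTIP1;1		Bv7ug180930_kzkq.t1	254	26.06	5.38	6
TIP	BvTIP1;2		Bv2g037380_iuuk.t1	252	26.3	5.92	6
TIP	BvTIP1;3		Bv7g176430_ynzf.t1	248	25.46	5.13	6
TIP	BvTIP2;1		Bv9g223310_dkzm.t1	247	25.26	5.6	6
TIP	BvTIP2;2		Bv5g104980_xunf.t1	249	25.09	4.7	7
TIP	BvTIP3;1		Bv8g190600_dreg.t1	257	27.13	7.07	5
TIP	BvTIP4;1		Bv2g032200_ydno.t1	247	26.1	6.57	6
TIP	BvTIP5;1		Bv3ug068240_gghp.t1	255	26.54	8.47	6
NIP	BvNIP1;1		Bv8ug202570_ughi.t1	292	30.87	8.91	6
NIP	BvNIP4;1		Bv2g027680_aejh.t1	273	29.3	8.87	6
NIP	BvNIP4;2		Bv2g027660_xash.t1	299	32.62	8.27	6
NIP	BvNIP5;1		Bv6TE021760_gkiq.t1	261	27.61	8.96	6
NIP	BvNIP5;2		Bv6g139140_oani.t1	298	30.9	8.73	6
NIP	BvNIP6;1		Bv9g225280_hmzo.t1	306	31.75	7.66	6
NIP	BvNIP6;2		Bv5g108450_zkgo.t1	266	27.46	7.82	6
NIP	BvNIP6;3		Bv5g108440_jecw.t1	327	35.08	9.03	6
NIP	BvNIP7;1		Bv3ug070540_kqew.t1	289	30.72	7.13	7
SIP	BvSIP1;1	alpha	Bv2g035790_zywx.t1	250	26.46	9.46	5
SIP	BvSIP1;1	beta	Bv2g035780_fzwq.t1	247	26.39	9.74	6
SIP	BvSIP2;1		Bv3g064810_qzqg.t1	236	26.02	9.56	5
XIP	BvXIP1;1		Bv9g217040_iwpe.t1	312	34.13	8.38	7
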