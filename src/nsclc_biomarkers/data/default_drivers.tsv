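# Canonical hotspot driver mutations excluded from TMB counting.
# Columns: gene <tab> protein change ("*" = any alteration in the gene).
EGFR	p.L858R
EGFR	p.T790M
EGFR	p.G719A
EGFR	p.G719C
EGFR	p.G719S
EGFR	p.S768I
EGFR	p.L861Q
EGFR	p.E746_A750del
EGFR	p.L747_P753delinsS
EGFR	p.A767_V769dup
EGFR	p.D770_N771insSVD
KRAS	p.G12C
KRAS	p.G12D
KRAS	p.G12V
KRAS	p.G13D
KRAS	p.Q61H
BRAF	p.V600E
PIK3CA	p.E545K
PIK3CA	p.H1047R
ALK	*
RET	*
ROS1	*
MET	p.D1228N
ERBB2	p.A775_G776insYVMA
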