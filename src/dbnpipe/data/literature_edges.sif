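# Literature-described signed interactions between EGFR- and SHH-pathway
# molecules (editable fixture; one directed edge per line: parent -> child).
# EGFR cascade
EGFR	->	p38
EGFR	->	AKT
EGFR	->	ERK
p38	->	CREB
p38	->	JUN
ERK	->	CREB
ERK	->	JUN
ERK	->	p70S6K
AKT	->	CREB
AKT	->	p70S6K
# EGFR -> SHH cross-talk
ERK	->	GLI1
ERK	->	GLI2
AKT	->	GLI1
# SHH pathway
SHH	->	PTCH1
PTCH1	->	GLI1
PTCH1	->	GLI2
HHIP	->	GLI1
HHIP	->	GLI2
GLI2	->	GLI1
SUFU	->	GLI1
SUFU	->	GLI2
GLI2	->	SUFU
# transcriptional feedback of GLI targets
GLI1	->	PTCH1
GLI1	->	HHIP
GLI2	->	PTCH1
GLI2	->	HHIP
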