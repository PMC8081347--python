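# PI3K/AKT pro-survival signaling network, alpha7 nAChR -> Bcl-2 readout.
# Curated from KEGG/PantherDB PI3K-AKT pathway membership and a p53 module
# (MYC, BIM, TP53, BAX, NOXA, PUMA) acting against the Bcl-2 branch.
# Node identities beyond the core pathway members are curated literature
# placeholders and some multi-step cascades are shortened to single edges
# (e.g. RAS->JNK, RAS->MYC); the graph is a topological model, not a
# comprehensive interactome.
#role CHRNA7 source
#role BCL2_ACT terminal
#role BCL2_INH terminal
#polarity BCL2_ACT +1
#polarity BCL2_INH -1
CHRNA7	activates	PI3K
CHRNA7	activates	JAK2
CHRNA7	activates	FYN
CHRNA7	activates	CAMKK2
CHRNA7	activates	RAS
PI3K	activates	AKT
JAK2	activates	AKT
FYN	activates	AKT
CAMKK2	activates	AKT
RAS	activates	AKT
RAS	activates	RAF
RAS	activates	RALGDS
RAS	activates	PLCE
RAS	activates	JNK
RAS	activates	MYC
AKT	activates	MTOR
AKT	activates	IKK
AKT	inhibits	GSK3B
AKT	activates	MDM2
RAF	activates	IKK
RALGDS	activates	MTOR
PLCE	activates	IKK
JNK	activates	BIM
MYC	activates	TP53
MTOR	activates	S6K1
IKK	activates	NFKB
GSK3B	inhibits	CREB
GSK3B	activates	BAD
MDM2	inhibits	FOXO3
TP53	activates	NOXA
TP53	activates	PUMA
BIM	activates	BAX
CREB	activates	BCL2_ACT
NFKB	activates	BCL2_ACT
S6K1	activates	BCL2_ACT
BAD	activates	BCL2_INH
FOXO3	activates	BCL2_INH
BAX	activates	BCL2_INH
NOXA	activates	BCL2_INH
PUMA	activates	BCL2_INH
BAD	inhibits	BCL2_ACT
BAX	inhibits	BCL2_ACT
FOXO3	inhibits	BCL2_ACT
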