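# USPS-style substitution table applied token-wise during component
# normalization, before any edit-distance computation.
# Format: RAW_TOKEN<TAB>CANONICAL_TOKEN.  Lines starting with '#' are comments.
ALLEY	ALY
AVENUE	AVE
AVENU	AVE
AV	AVE
BOULEVARD	BLVD
BOULV	BLVD
CENTER	CTR
CENTRE	CTR
CIRCLE	CIR
COURT	CT
CRESCENT	CRES
DRIVE	DR
DRV	DR
EXPRESSWAY	EXPY
FREEWAY	FWY
GROVE	GRV
HEIGHTS	HTS
HIGHWAY	HWY
JUNCTION	JCT
LANE	LN
LOOP	LOOP
MOUNT	MT
MOUNTAIN	MTN
PARKWAY	PKWY
PIKE	PIKE
PLACE	PL
PLAZA	PLZ
POINT	PT
RIDGE	RDG
ROAD	RD
RD	RD
ROUTE	RTE
SAINT	ST
SQUARE	SQ
STREET	ST
STR	ST
TERRACE	TER
TRAIL	TRL
TURNPIKE	TPKE
WAY	WAY
NORTH	N
SOUTH	S
EAST	E
WEST	W
NORTHEAST	NE
NORTHWEST	NW
SOUTHEAST	SE
SOUTHWEST	SW
FORT	FT
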