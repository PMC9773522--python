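x_gene	y_gene
AMELX	AMELY
CDYL	CDY1
DDX3X	DDX3Y
EIF1AX	EIF1AY
HSFX1	HSFY1
KDM5C	KDM5D
KDM6A	UTY
NLGN4X	NLGN4Y
PCDH11X	PCDH11Y
PRKX	PRKY
RBMX	RBMY1A1
RPS4X	RPS4Y1
SOX3	SRY
TBL1X	TBL1Y
TGIF2LX	TGIF2LY
TMSB4X	TMSB4Y
TSPYL2	TSPY1
TXLNG	TXLNGY
USP9X	USP9Y
VCX	VCY
XKRX	XKRY
ZFX	ZFY
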