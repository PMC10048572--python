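line	source	locus	alleles
WIL2S	ATCC	AMELO	X,Y
WIL2S	ATCC	CSF1PO	11,12
WIL2S	ATCC	D13S317	11
WIL2S	ATCC	D16S539	11,12
WIL2S	ATCC	D5S818	12,13
WIL2S	ATCC	D7S820	9,11
WIL2S	ATCC	TH01	8,9.3
WIL2S	ATCC	TPOX	8,11
WIL2S	ATCC	vWA	17,20
WIL2S	OWN	AMELO	X,Y
WIL2S	OWN	CSF1PO	11,12
WIL2S	OWN	D13S317	11
WIL2S	OWN	D16S539	11,12
WIL2S	OWN	D5S818	12,13
WIL2S	OWN	D7S820	9,11
WIL2S	OWN	TH01	8,9.3
WIL2S	OWN	TPOX	8,11
WIL2S	OWN	vWA	17,20
WIL2S	OWN	D1S1656	14,15.3
WIL2S	OWN	D2S441	12,15
WIL2S	OWN	D3S1358	16
WIL2S	OWN	D8S1179	10,13
WIL2S	OWN	D10S1248	14,16
WIL2S	OWN	D12S391	17,22
WIL2S	OWN	D18S51	11,16
WIL2S	OWN	D21S11	28
WIL2S	OWN	D22S1045	15,16
WIL2S	OWN	FGA	20,22
WIL2S	OWN	SE33	16,18
JURKAT	ATCC	AMELO	X,Y
JURKAT	ATCC	CSF1PO	11,12
JURKAT	ATCC	D13S317	8,12
JURKAT	ATCC	D16S539	11
JURKAT	ATCC	D5S818	9
JURKAT	ATCC	D7S820	8,12
JURKAT	ATCC	TH01	6,9.3
JURKAT	ATCC	TPOX	8,10
JURKAT	ATCC	vWA	18
JURKAT	OWN	AMELO	X,Y
JURKAT	OWN	CSF1PO	11,12
JURKAT	OWN	D13S317	8,12
JURKAT	OWN	D16S539	11
JURKAT	OWN	D5S818	9
JURKAT	OWN	D7S820	8,12
JURKAT	OWN	TH01	6,9.3
JURKAT	OWN	TPOX	8,10
JURKAT	OWN	vWA	18
JURKAT	OWN	D1S1656	15.3,16.3
JURKAT	OWN	D2S441	15,16
JURKAT	OWN	D3S1358	15
JURKAT	OWN	D8S1179	13,14
JURKAT	OWN	D10S1248	14,16
JURKAT	OWN	D12S391	22,23
JURKAT	OWN	D18S51	12.2,21
JURKAT	OWN	D21S11	30.2,32.2
JURKAT	OWN	D22S1045	14,17
JURKAT	OWN	FGA	20.2,21.2
JURKAT	OWN	SE33	16,18
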