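species	type	genes
Oryza sativa	segmental	OsRRB2/OsRRB6
Oryza sativa	segmental	OsRRB3/OsRRB5
Panicum hallii	segmental	PhRRB2/PhRRB3
Sorghum bicolor	segmental	SbRRB4/SbRRB11
Sorghum bicolor	segmental	SbRRB5/SbRRB8
Sorghum bicolor	tandem	SbRRB9/SbRRB10
Setaria italica	segmental	SiRRB2/SiRRB3
Setaria italica	tandem	SiRRB4/SiRRB5
Zea mays	segmental	ZmRRB1/ZmRRB9
Zea mays	segmental	ZmRRB3/ZmRRB6
Zea mays	segmental	ZmRRB5/ZmRRB7
Triticum aestivum	segmental	TaRRB1/TaRRB2
Triticum aestivum	segmental	TaRRB1/TaRRB3
Triticum aestivum	segmental	TaRRB2/TaRRB3
Triticum aestivum	segmental	TaRRB4/TaRRB5
Triticum aestivum	segmental	TaRRB4/TaRRB6
Triticum aestivum	segmental	TaRRB5/TaRRB6
Triticum aestivum	segmental	TaRRB7/TaRRB9
Triticum aestivum	segmental	TaRRB7/TaRRB11
Triticum aestivum	segmental	TaRRB8/TaRRB10
Triticum aestivum	segmental	TaRRB8/TaRRB12
Triticum aestivum	segmental	TaRRB8/TaRRB15
Triticum aestivum	segmental	TaRRB8/TaRRB16
Triticum aestivum	segmental	TaRRB8/TaRRB17
Triticum aestivum	segmental	TaRRB9/TaRRB11
Triticum aestivum	segmental	TaRRB10/TaRRB12
Triticum aestivum	segmental	TaRRB10/TaRRB15
Triticum aestivum	segmental	TaRRB10/TaRRB16
Triticum aestivum	segmental	TaRRB10/TaRRB17
Triticum aestivum	segmental	TaRRB12/TaRRB15
Triticum aestivum	segmental	TaRRB12/TaRRB16
Triticum aestivum	segmental	TaRRB12/TaRRB17
Triticum aestivum	segmental	TaRRB15/TaRRB16
Triticum aestivum	segmental	TaRRB15/TaRRB17
Triticum aestivum	segmental	TaRRB16/TaRRB17
Triticum aestivum	tandem	TaRRB13/TaRRB14/TaRRB15
Triticum aestivum	tandem	TaRRB17/TaRRB18
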