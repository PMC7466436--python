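# emotion<TAB>keyword (lowercase; inflectional variants listed explicitly)
sadness	trauer
sadness	traurig
sadness	traurigkeit
sadness	trauriges
sadness	traurige
fear	angst
fear	ängstlich
fear	furcht
fear	ängste
fear	angsthaft
anger	wut
anger	wütend
anger	zorn
anger	ärger
anger	wütende
happiness	freude
happiness	glück
happiness	glücklich
happiness	froh
happiness	fröhlich
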