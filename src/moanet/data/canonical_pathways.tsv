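canonical_id	pattern	categories
cell cycle	cell cycle	cell cycle/proliferation/apoptosis
cell cycle	mitotic	cell cycle/proliferation/apoptosis
cell cycle	apoptosis	cell cycle/proliferation/apoptosis
cell cycle	apoptotic	cell cycle/proliferation/apoptosis
cell cycle	caspase	cell cycle/proliferation/apoptosis
Hippo	hippo	cell cycle/proliferation/apoptosis;metastasis/invasion
Myc	\bmyc\b	cell cycle/proliferation/apoptosis
Notch	notch	cell cycle/proliferation/apoptosis;metastasis/invasion
NRF2	nrf2	cell cycle/proliferation/apoptosis
NRF2	nuclear receptor meta-pathway	cell cycle/proliferation/apoptosis
PI3K/Akt	pi3k	cell cycle/proliferation/apoptosis
PI3K/Akt	pi-3-kinase	cell cycle/proliferation/apoptosis
PI3K/Akt	\bakt\b	cell cycle/proliferation/apoptosis
PI3K/Akt	mtor	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	mapk	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	\begfr?\b	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	erbb	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	pdgf	cell cycle/proliferation/apoptosis;metastasis/invasion
RTK-RAS-MAPK	\bptk6\b	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	\bk?ras\b	cell cycle/proliferation/apoptosis
RTK-RAS-MAPK	vegf	angiogenesis
TGF-beta	tgf	cell cycle/proliferation/apoptosis;metastasis/invasion
p53	\bt?p53\b	cell cycle/proliferation/apoptosis
Wnt/beta-catenin	\bwnt\b	cell cycle/proliferation/apoptosis;metastasis/invasion
Wnt/beta-catenin	beta-catenin	cell cycle/proliferation/apoptosis;metastasis/invasion
Wnt/beta-catenin	tcf dependent	cell cycle/proliferation/apoptosis;metastasis/invasion
immune	interferon	cell cycle/proliferation/apoptosis
immune	\btnf\b	cell cycle/proliferation/apoptosis
immune	tnf alpha	cell cycle/proliferation/apoptosis
immune	interleukin	cell cycle/proliferation/apoptosis
immune	\bil-?\d+\b	cell cycle/proliferation/apoptosis
immune	cytokine	cell cycle/proliferation/apoptosis
immune	chemokine	cell cycle/proliferation/apoptosis;metastasis/invasion
immune	t[ -]cell receptor	cell cycle/proliferation/apoptosis
immune	b[ -]cell receptor	cell cycle/proliferation/apoptosis
immune	toll-like	cell cycle/proliferation/apoptosis
immune	\btlr\d*\b	cell cycle/proliferation/apoptosis
immune	rig-i	cell cycle/proliferation/apoptosis
immune	fc epsilon	cell cycle/proliferation/apoptosis
immune	inflammatory response	cell cycle/proliferation/apoptosis
immune	nf-kb	cell cycle/proliferation/apoptosis
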