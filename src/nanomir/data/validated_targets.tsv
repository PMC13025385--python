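mirna	gene	evidence	source_note
miR-146a-5p	TRAF6	validated	luciferase reporter assay; top-ranked prediction
miR-146a-5p	IRAK1	validated	luciferase reporter assay; top-ranked prediction
miR-146a-5p	SMAD4	validated	NF-kB feedback node
miR-146a-5p	WASF2	validated	conserved 3'-UTR site; shared target
miR-4286	TGFB1	validated	experimentally validated interaction
miR-4286	TGFBR2	validated	experimentally validated interaction
miR-4286	RUNX3	validated	experimentally validated interaction
miR-4286	HDAC3	validated	experimentally validated interaction
miR-4286	WASF2	validated	conserved 3'-UTR site; shared target
miR-4286	PTEN	predicted	highly ranked prediction
miR-4286	MAP3K1	predicted	highly ranked prediction
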