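annotation_cluster	source	enrichment_category	count	p_value	fdr
1	GOTERM_CC_FAT	Cell junction	4	1.7e-2	8.2e-1
1	GOTERM_CC_FAT	Plasma membrane part	7	2.2e-2	6.8e-1
1	GOTERM_CC_FAT	Plasma membrane	7	2.1e-1	9.3e-1
2	GOTERM_CC_FAT	Cytoskeletal part	4	8.1e-2	8.1e-1
2	GOTERM_CC_FAT	Cytoskeleton	4	1.9e-1	9.2e-1
2	GOTERM_CC_FAT	Intracellular non-membrane-bound organelle	4	5.6e-1	1.0
2	GOTERM_CC_FAT	Non-membrane-bound organelle	4	5.6e-1	1.0
3	SP_PIR_KEYWORDS	Membrane	9	2.0e-1	9.6e-1
3	GOTERM_CC_FAT	Integral to plasma membrane	3	3.8e-1	9.9e-1
3	GOTERM_CC_FAT	Intrinsic to plasma membrane	3	3.9e-1	9.9e-1
3	UP_SEQ_FEATURE	Topological domain: Cytoplasmic	5	4.0e-1	1.0
3	UP_SEQ_FEATURE	Transmembrane region	6	5.1e-1	1.0
3	SP_PIR_KEYWORDS	Transmembrane	6	5.2e-1	9.9e-1
3	GOTERM_CC_FAT	Intrinsic to membrane	7	6.0e-1	1.0
3	UP_SEQ_FEATURE	Topological domain: Extracellular	3	7.5e-1	1.0
3	GOTERM_CC_FAT	Integral to membrane	6	7.6e-1	1.0
4	UP_SEQ_FEATURE	Glycosylation site: N-linked (GlcNAc)	6	3.5e-1	1.0
4	SP_PIR_KEYWORDS	Signal	5	3.6e-1	9.9e-1
4	UP_SEQ_FEATURE	Signal peptide	5	3.7e-1	1.0
4	SP_PIR_KEYWORDS	Glycoprotein	6	3.8e-1	9.9e-1
4	UP_SEQ_FEATURE	Disulfide bond	3	7.7e-1	1.0
4	SP_PIR_KEYWORDS	Disulfide bond	3	7.8e-1	1.0
5	SP_PIR_KEYWORDS	Metal-binding	4	5.4e-1	9.9e-1
5	GOTERM_MF_FAT	Metal ion binding	5	8.0e-1	1.0
5	GOTERM_MF_FAT	Cation binding	5	8.1e-1	1.0
5	GOTERM_MF_FAT	Ion binding	5	8.2e-1	1.0
5	GOTERM_MF_FAT	Transition metal ion binding	3	8.9e-1	1.0
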