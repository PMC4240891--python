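# Monocyte/dendritic-cell (M/D) metagene membership, 19 genes.
# The nine MHC class II antigen-presentation genes and CSF1R carry their
# real symbols; the remaining nine members are synthetic stand-in symbols
# (MDSYN*) because the full published membership list is not bundled.
gene_symbol	annotation
HLA-DRA	mhc_class_ii_antigen_presentation
HLA-DRB1	mhc_class_ii_antigen_presentation
HLA-DMA	mhc_class_ii_antigen_presentation
HLA-DMB	mhc_class_ii_antigen_presentation
HLA-DPA1	mhc_class_ii_antigen_presentation
HLA-DPB1	mhc_class_ii_antigen_presentation
HLA-DQA1	mhc_class_ii_antigen_presentation
HLA-DQB1	mhc_class_ii_antigen_presentation
CD74	mhc_class_ii_antigen_presentation
CSF1R	myeloid_growth_factor_receptor
MDSYN01	synthetic_standin
MDSYN02	synthetic_standin
MDSYN03	synthetic_standin
MDSYN04	synthetic_standin
MDSYN05	synthetic_standin
MDSYN06	synthetic_standin
MDSYN07	synthetic_standin
MDSYN08	synthetic_standin
MDSYN09	synthetic_standin
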