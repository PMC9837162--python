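# Published group-level summaries of TBP-promoter KD (nM) for plant
# promoters of genes homologous to the wheat allergens globulin, albumin
# and beta-amylase: promoter count N, arithmetic mean M0 and standard
# error of the mean, for food vs non-food plant species.
family	group	n	m0_nM	sem_nM
globulin	food	74	2.97	0.21
globulin	non_food	53	2.15	0.08
albumin	food	84	3.10	0.22
albumin	non_food	37	2.18	0.10
beta_amylase	food	77	2.85	0.21
beta_amylase	non_food	38	3.89	0.32
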