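gene_symbol	chrom	gene_start	gene_end	lipid_trait	drug_label
HMGCR	5	74632154	74657929	LDL	statins
PCSK9	1	55505221	55530525	LDL	alirocumab
NPC1L1	7	44552134	44580914	LDL	ezetimibe
APOB	2	21224301	21266945	LDL	mipomersen
ANGPTL3	1	63063158	63071830	LDL	evinacumab
PPARA	22	46546424	46639653	LDL	fenofibrate
LDLR	19	11200038	11244506	LDL	LDL-receptor modulation
LPL	8	19759228	19824769	LDL	lipoprotein-lipase modulation
ANGPTL3	1	63063158	63071830	TG	evinacumab
PPARA	22	46546424	46639653	TG	fenofibrate
APOC3	11	116700623	116703788	TG	volanesorsen
LDLR	19	11200038	11244506	TG	LDL-receptor modulation
LPL	8	19759228	19824769	TG	lipoprotein-lipase modulation
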