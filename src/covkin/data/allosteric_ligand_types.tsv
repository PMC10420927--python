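ligand_type	binding_site_description	count	baseline_count
III	Adjacent to ATP site	92	81
IV	Distant from ATP site	91	81
V	ATP site + allosteric site	15	15
VI	Allosteric site	13	10
activator	Allosteric site	20	19
multi_site	ATP site and/or allosteric site(s)	31	26
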