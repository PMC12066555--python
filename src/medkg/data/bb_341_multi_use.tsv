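Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
beta-blockers	MT		heart failure	Diseases		forward	Indications	Indications
beta-blockers	MT		congestive heart failure	Diseases		forward	Indications	Indications
beta-blockers	MT		metoprolol	Drugs		forward	Contains	Contains
heart failure	Diseases		metoprolol	Drugs		reverse	Treatment	Treatment
beta-blockers	MT		β-Indications	Indications		forward	AT	AT
β-Indications	Indications		hypertension	Diseases		forward	Indications	Indications
β-Indications	Indications		hereditary long QT	Diseases		forward	Indications	Indications
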