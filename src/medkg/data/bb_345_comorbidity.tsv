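Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
intravenous beta-blockers	Drugs		hypertension	Diseases		forward	Treatment	Treatment
hypertension combined with diabetes	Complications		hypertension	Diseases		forward	Contains	Contains
hypertension combined with diabetes	Complications		diabetes	Diseases		forward	Contains	Contains
beta-blockers	MT		hypertension combined with diabetes	Complications		forward	Contraindications	Contraindications
ACEI	Drug combinations		hypertension	Diseases		forward	Treatment	Treatment
angiotensin II receptor blockers	Drug combinations		hypertension	Diseases		forward	Treatment	Treatment
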