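Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
propranolol	Drugs		hypertension	Diseases		forward	Indications	Indications
propranolol	Drugs		myocardial infarction	Diseases		forward	Indications	Indications
hypertension	Diseases		initial dose of 10 mg	Drug applications		forward	Properties	Properties
hypertension	Diseases		maximum dosage of 200 mg	Drug applications		forward	Properties	Properties
hypertension	Diseases		3–4 times daily	Drug applications		forward	Properties	Properties
myocardial infarction	Diseases		dosage range of 30–240 mg	Drug applications		forward	Properties	Properties
myocardial infarction	Diseases		2–3 times daily	Drug applications		forward	Properties	Properties
propranolol	Drugs		tablet form	Drug applications		forward	Properties	Properties
propranolol	Drugs		sinus bradycardia	Adverse reactions		forward	Causes	Causes
propranolol	Drugs		atrioventricular block	Adverse reactions		forward	Causes	Causes
propranolol	Drugs		hypotension	Adverse reactions		forward	Causes	Causes
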