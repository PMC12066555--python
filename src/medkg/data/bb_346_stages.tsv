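Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
hypertension	Diseases		grade I hypertension	Diseases		forward	Stage	Stage
hypertension	Diseases		grade II hypertension	Diseases		forward	Stage	Stage
hypertension	Diseases		grade III hypertension	Diseases		forward	Stage	Stage
grade I hypertension	Diseases		grade II hypertension	Diseases		forward	Stage	Stage
grade II hypertension	Diseases		grade III hypertension	Diseases		forward	Stage	Stage
lifestyle interventions	Treatment methods		grade I hypertension	Diseases		forward	Treatment	Treatment
ARNI or diuretic monotherapy after 4–12 weeks	Treatment methods		grade I hypertension	Diseases		forward	Treatment	Treatment
ARNI or diuretic monotherapy	Treatment methods		grade II hypertension	Diseases		forward	Treatment	Treatment
intensive combination therapy	Treatment methods		grade III hypertension	Diseases		forward	Treatment	Treatment
grade III hypertension	Diseases		target organ damage risk	Drug effects		forward	Causes	Causes
ARNI	Drugs		grade II hypertension	Diseases		forward	Treatment	Treatment
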