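Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
sinus bradycardia	Symptoms		bradycardia	Symptoms		forward	Shows	Shows
sinus bradycardia	Symptoms		cardiogenic syncope	Symptoms		forward	Shows	Shows
atrial fibrillation	Symptoms		bradycardia	Symptoms		forward	Shows	Shows
atrial fibrillation	Symptoms		frequent premature contractions	Symptoms		forward	Shows	Shows
β-receptor blockers	MT		bradycardia	Symptoms		forward	Treatment	Treatment
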