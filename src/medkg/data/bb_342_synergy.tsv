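Entity1	Type1	Attribute1	Entity2	Type2	Attribute2	Direction	R_name	R_label
congestive heart failure	Diseases		beta-blockers combined with felodipine	Drug combinations		forward	The combined effect is better than	Effects
congestive heart failure	Diseases		beta-blockers combined with felodipine	Drug combinations		forward	The combined effect is better than	Effects
congestive heart failure	Diseases		beta-blockers combined with felodipine	Drug combinations		forward	The combined effect is better than	Effects
beta-blockers combined with felodipine	Drug combinations		metoprolol	Drugs		forward	Drug combination	Drug combination
beta-blockers combined with felodipine	Drug combinations		bisoprolol	Drugs		forward	Drug combination	Drug combination
beta-blockers combined with felodipine	Drug combinations		carvedilol	Drugs		forward	Drug combination	Drug combination
beta-blockers combined with felodipine	Drug combinations		felodipine	Drugs		forward	Drug combination	Drug combination
beta-blockers combined with felodipine	Drug combinations		reduces systemic vascular resistance	Drug effects		forward	Effects	Effects
beta-blockers combined with felodipine	Drug combinations		increases ejection fraction	Drug effects		forward	Effects	Effects
digoxin	Drugs		congestive heart failure	Diseases		forward	Treatment	Treatment
digoxin	Drugs		rapid heartbeats	Symptoms		forward	Improves	Improves
sodium nitroprusside	Drugs		rapid heartbeats	Symptoms		forward	Improves	Improves
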