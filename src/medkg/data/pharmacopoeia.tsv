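term	alias_of
propranolol
metoprolol
carvedilol
bisoprolol
labetalol
felodipine
nifedipine
verapamil
digoxin
sodium nitroprusside
aspirin
atorvastatin
captopril
enalapril
ACEI
beta-blockers
intravenous beta-blockers
intravenous verapamil
ACE inhibitors	ACEI
angiotensin-converting enzyme inhibitors	ACEI
β-blockers	beta-blockers
β-receptor blockers	beta-blockers
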