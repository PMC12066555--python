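mt	amt_name	concept_term
beta-blockers	β-Special beta blockers	Drug
beta-blockers	β-Ultra short acting intravenous	Drug
beta-blockers	β-Nebivolol	Drug
beta-blockers	β-Other drug relationships	Drug combinations
beta-blockers	β-Angina pectoris	Diseases
beta-blockers	β-Acute ST segment elevation myocardial infarction	Diseases
beta-blockers	β-Personnel	Patients
beta-blockers	β-Combination medication	Combination medications
beta-blockers	β-Catecholaminergic	Combination medications
beta-blockers	β-Mechanism of action	Behaviors
beta-blockers	β-Pharmacological properties	Behaviors
beta-blockers	β-Pharmacokinetic characteristics	Behaviors
beta-blockers	β-Function	Behaviors
beta-blockers	β-Treatment of primary hypertension	Treatment methods
beta-blockers	β-Treatment of arrhythmia	Treatment methods
beta-blockers	β-The research status of the prognosis of angina pectoris with β	Research
beta-blockers	β-Description	Research
beta-blockers	β-Experimental study description	Research
beta-blockers	β-Application in heart failure	Drug applications
beta-blockers	β-Doseage of medication	Drug applications
beta-blockers	β-Dose	Drug applications
beta-blockers	β-Apply	Drug applications
beta-blockers	β-Route of administration	Drug applications
beta-blockers	β-Medication cycle	Drug applications
beta-blockers	β-Medication frequency	Drug applications
beta-blockers	β-Complications and selections	Complication
beta-blockers	β-Contra indications	Contraindications
beta-blockers	β-From the past to the future	Report
beta-blockers	β-Biochemical substances	Report
beta-blockers	β-Cardiovascular effects	Drug effects
beta-blockers	β-Description of resistance to beta blockers	Drug effects
beta-blockers	β-Intolerance	Drug effects
beta-blockers	β-Tolerance	Drug effects
beta-blockers	β-Competitive blocking effect	Drug effects
beta-blockers	β-Indications	Indications
beta-blockers	β-Acute coronary syndrome	Symptom
beta-blockers	β-Other cardiac indications	Symptom
beta-blockers	β-Noncardiac indications	Symptom
beta-blockers	β-Excessive use	Symptom
beta-blockers	β-Risk	Drug contraindications
beta-blockers	β-Adverse reactions	Adverse reactions
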