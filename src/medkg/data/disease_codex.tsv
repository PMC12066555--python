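term	alias_of
hypertension
glaucoma
ethanol withdrawal
adenylate cyclase
angina pectoris
exertional angina pectoris
myocardial infarction
acute myocardial infarction
heart failure
congestive heart failure
hereditary long QT
atrial fibrillation
sinus bradycardia
bradycardia
cardiogenic syncope
diabetes
arrhythmia
high blood pressure	hypertension
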