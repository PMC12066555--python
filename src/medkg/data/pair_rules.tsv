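subject_category	object_category	relations
Disease	Disease	Contain
Drug	AMT	Type attribute (AT);Drug relationship;Combined use;The combined effect is better than
Patient	AMT	Add;Use;Give;Contraindications to;Composition;Initial treatment;Beneficial;Intolerable;Try to give;Standard treatment
Drug combination	Drug	Combination medication;Include;Drug combination
Drug effect	AMT	Description;Drug relationship;Efficacy comparison;Adverse reactions;Effect;Application strategy
Drug effect	Drug characteristics	Drug comparison;Efficacy comparison
Drug effect	Drug	Drug relationship;Should
Drug category	AMT	Interaction exists;Acts;Is not;Belongs to
MT	AMT	Type attribute (AT)
Symptom	AMT	Relieve;Affect;Aggravate;Cannot effectively relieve;Indication;Inhibit;Lower blood pressure;Cause;May aggravate;Application description
Treatment method	AMT	Treatment;Use with caution;Application;Application description;Indication
Treatment method	Symptom	Is;Relieve;Improve
Disease	Disease stage	Stage
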