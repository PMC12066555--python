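concept	aliases	sources
Drugs	Drug	G;EC;St;Sc
Drug combinations		G;EC;St;Sc
Diseases	Disease	G;EC;St;Sc
Patients	Patient	G
Combination medications		G;EC;St;Sc
Behaviors	Behavior	G;EC;St;Sc
Therapeutic approaches	Treatment methods;Treatment method	G;EC;St;Sc;EE
Research		G;St;Sc
Drug applications		G;EC;St;Sc;EE
Complications	Complication	G;EC;St;Sc
Contraindications		G;EC;St;Sc
Reports	Report	G;St;Sc
Drug effects	Results	G;EC;St;Sc;R;EE
Indications		G;EC;St;Sc
Symptoms	Symptom	G;EC;St;Sc;R;EE
Drug contraindications		G;EC;St;Sc;R
Adverse reactions		G;EC;St;Sc;R
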