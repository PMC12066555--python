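relation	sources
Contains	G;EC
Description	G;EC
Indications (Drugs)	G;EC
Equivalent description	G;EC;R
AT	G;EC
Combination medication	G;EC
Treatment	G;EC
Action	G;EC;R
Effects	G;EC;R
Indications	G;EC
Drug combination	G;EC
Contraindications	G;EC
Properties	G;EC;R
Causes	G;EC;R
Improves	G;EC;R
Shows	G;EC
Stage	G;EC
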