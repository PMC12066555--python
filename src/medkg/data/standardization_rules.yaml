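# Term standardization rules: five kinds, applied in the listed kind order.
rules:
  - kind: category_unification
    pattern: "Short-acting nitrates"
    replacement: ["nitrate drugs"]
  - kind: category_unification
    pattern: "Long-acting nitrates"
    replacement: ["nitrate drugs"]
  - kind: synonym
    pattern: "ACE inhibitors"
    replacement: ["ACEI"]
  - kind: synonym
    pattern: "Angiotensin-converting enzyme inhibitors"
    replacement: ["ACEI"]
  - kind: expression_normalization
    pattern: "Research status of angina pectoris prognosis"
    replacement: ["Angina pectoris prognosis study"]
  - kind: reference_fill
    pattern: "Intravenous beta-blockers or verapamil"
    replacement: ["Intravenous beta-blockers", "Intravenous verapamil"]
  - kind: redundancy_simplification
    pattern: "Complications related to hypertension"
    replacement: ["Hypertension complications"]
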