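{
  "description": "Published riboflavin validation measurements for L. plantarum MTCC 25432: experimental vs fuzzy-model-predicted riboflavin (ug/L). 'validation' pairs are the held-out mid-range checks; 'dose_response' pairs are curve points quoted alongside them.",
  "baseline_production": 346.0,
  "optimized_production": 429.0,
  "pairs": [
    {"factor": "casamino", "level": 11, "experimental": 386.915, "predicted": 384, "source": "validation"},
    {"factor": "gtp", "level": 0.03, "experimental": 403.18, "predicted": 402, "source": "validation"},
    {"factor": "sodium_acetate", "level": 12, "experimental": 385.14, "predicted": 382, "source": "validation"},
    {"factor": "glycine", "level": 12, "experimental": 380.69, "predicted": 383, "source": "validation"},
    {"factor": "casamino", "level": 5, "experimental": 360.93, "predicted": 368, "source": "dose_response"},
    {"factor": "gtp", "level": 0.02, "experimental": 391.495, "predicted": 398, "source": "dose_response"}
  ]
}
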