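{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pvscreen two-phase study report",
  "type": "object",
  "required": ["seeds", "phase1", "phase2", "comparators"],
  "properties": {
    "seeds": {
      "type": "object",
      "required": ["phase1", "phase2"],
      "properties": {
        "phase1": {"type": "integer"},
        "phase2": {"type": "integer"}
      }
    },
    "phase1": {
      "type": "object",
      "required": ["flow", "who_rate_pct", "cutoffs", "raw_rule", "rounded_rule"],
      "properties": {
        "flow": {
          "type": "object",
          "required": ["total", "who_positive", "dna_failures", "tested",
                       "mutation_positive", "known_mpn_excluded", "new_positives"],
          "properties": {
            "total": {"type": "integer"},
            "who_positive": {"type": "integer"},
            "dna_failures": {"type": "integer"},
            "tested": {"type": "integer"},
            "mutation_positive": {"type": "integer"},
            "known_mpn_excluded": {"type": "integer"},
            "new_positives": {"type": "integer"}
          }
        },
        "who_rate_pct": {"type": "number"},
        "cutoffs": {"type": "array"},
        "raw_rule": {
          "type": "object",
          "required": ["neutrophils_gt", "platelets_gt"],
          "properties": {
            "neutrophils_gt": {"type": "number"},
            "platelets_gt": {"type": "number"}
          }
        },
        "rounded_rule": {
          "type": "object",
          "required": ["neutrophils_gt", "platelets_gt"],
          "properties": {
            "neutrophils_gt": {"type": "number"},
            "platelets_gt": {"type": "number"}
          }
        }
      }
    },
    "phase2": {
      "type": "object",
      "required": ["flow", "performance", "who_rate_pct", "step2_rate_pct"],
      "properties": {
        "flow": {
          "type": "object",
          "required": ["total", "who_positive", "step2_positive", "dna_failures",
                       "tested", "mutation_positive", "known_mpn_excluded",
                       "new_positives"]
        },
        "performance": {
          "type": "object",
          "required": ["who_rate", "step2_rate_of_total", "yield_of_tested",
                       "prevalence_in_who_stratum", "prevalence_in_total",
                       "ppv", "nnt", "workload_fraction"]
        },
        "who_rate_pct": {"type": "number"},
        "step2_rate_pct": {"type": "number"}
      }
    },
    "comparators": {
      "type": "object",
      "required": ["rumi", "canadian"]
    }
  }
}
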