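{
  "type": "object",
  "properties": {
    "config": {"type": "object"},
    "n_participants": {"type": "number"},
    "h1": {
      "type": "object",
      "properties": {
        "tau": {"type": "number"},
        "bf10": {"type": "number"},
        "verdict": {"type": "string"}
      }
    },
    "h2": {
      "type": "object",
      "nullable": true,
      "properties": {
        "bf10": {"type": "number"},
        "mc_error": {"type": "number"},
        "verdict": {"type": "string"}
      }
    },
    "h3": {
      "type": "object",
      "nullable": true,
      "properties": {
        "bf10_combined": {"type": "number"},
        "replication_bf": {"type": "number"},
        "verdict": {"type": "string"}
      }
    },
    "quality_controls": {
      "type": "object",
      "properties": {
        "floor_effect": {
          "type": "object",
          "properties": {
            "statistic": {"type": "number"},
            "p_value": {"type": "number"},
            "non_discernable_from_random": {"type": "boolean"}
          }
        },
        "test_retest": {"type": "object"},
        "manipulation_check": {
          "type": "object",
          "properties": {
            "per_ri": {"type": "array"},
            "monotone_in_ri": {"type": "boolean"}
          }
        },
        "difficulty_bootstrap": {
          "type": "object",
          "properties": {
            "mean_diff_deg": {"type": "number"},
            "ci95": {"type": "array"},
            "n_boot": {"type": "number"}
          }
        }
      }
    }
  }
}
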