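{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fluxstress analysis report",
  "type": "object",
  "required": ["kind", "tests", "provenance", "dose_response"],
  "properties": {
    "kind": {"enum": ["confound", "atp_budget"]},
    "group_summaries": {"type": ["array", "null"]},
    "combined_summary": {"type": ["array", "null"]},
    "underestimation": {"type": ["array", "null"]},
    "underestimation_per_experiment": {"type": ["array", "null"]},
    "dose_response": {"type": "object"},
    "parameter_changes": {"type": ["array", "null"]},
    "atp_budget": {"type": ["array", "null"]},
    "atp_folds": {"type": ["array", "null"]},
    "tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["test", "label", "statistic", "df", "p"]
      }
    },
    "confound_flags": {"type": "object"},
    "provenance": {
      "type": "object",
      "required": ["config_hash", "package_version"]
    }
  }
}
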