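{
  "schema_version": 1,
  "description": "Interface payloads emitted by the sepcue engine. Every payload carries the query state identity, an inputs digest, and a list of cue objects; each cue object has a cue_code (R1..R8, with -L/-M/-H or -Y/-N suffixes where applicable) and cue-specific fields.",
  "required_fields": [
    "schema_version",
    "interface_name",
    "patient_id",
    "bin_index",
    "selected_plan",
    "no_recommendation",
    "inputs_digest",
    "cues"
  ],
  "interface_cues": {
    "case_features": ["R1", "R2"],
    "treatment_risk": ["R3"],
    "mortality_risk": ["R3"],
    "interactive_treatment_risk": ["R7", "R3", "R4", "R5"],
    "interactive_mortality_risk": ["R7", "R3", "R4", "R5"],
    "prior_clinician_actions": ["R7", "R5", "R6"],
    "treatment_recommendation": ["R7", "R8"]
  },
  "optional_cues": {
    "interactive_treatment_risk": ["R8"],
    "interactive_mortality_risk": ["R8"],
    "prior_clinician_actions": ["R8"]
  },
  "cue_fields": {
    "R1": ["kind", "entries"],
    "R2": ["kind", "entries"],
    "R3": ["outcome_kind", "probability", "n_defined", "level"],
    "R4": ["plan", "outcome_kind", "risk_plan", "risk_rest", "n_plan", "n_rest", "p_value", "significant", "sufficient_support"],
    "R5": ["category"],
    "R6": ["category", "modal_action", "modal_frequency", "consensus"],
    "R7": ["plan"],
    "R8": ["mode", "plan"]
  }
}
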