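{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Compliance report",
  "type": "object",
  "required": [
    "message_ref",
    "tier",
    "verdict",
    "verdicts",
    "outcomes",
    "timestamp",
    "toolkit_version",
    "catalog_version"
  ],
  "properties": {
    "message_ref": {"type": "string"},
    "tier": {"enum": ["minimal", "general", "optional"]},
    "verdict": {"enum": ["pass", "fail"]},
    "verdicts": {
      "type": "object",
      "additionalProperties": {"enum": ["pass", "fail"]}
    },
    "outcomes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["rule_id", "tier", "severity", "status", "evidence", "corrective_action"],
        "properties": {
          "rule_id": {"type": "string"},
          "tier": {"enum": ["minimal", "general", "optional"]},
          "severity": {"enum": ["error", "warning", "info"]},
          "status": {"enum": ["pass", "fail", "not_evaluated"]},
          "evidence": {"type": "string"},
          "corrective_action": {"type": "string"}
        }
      }
    },
    "timestamp": {"type": "string"},
    "toolkit_version": {"type": "string"},
    "catalog_version": {"type": "string"}
  }
}
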