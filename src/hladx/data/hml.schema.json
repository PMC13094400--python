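{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Minimal-HML message (JSON serialization)",
  "type": "object",
  "required": ["hml"],
  "properties": {
    "hml": {
      "type": "object",
      "required": ["message_id", "samples"],
      "properties": {
        "version": {"type": "string"},
        "message_id": {"type": "string", "minLength": 1},
        "created": {"type": "string"},
        "reporting_center": {"type": "string"},
        "extras": {"type": "array", "items": {"type": "string"}},
        "samples": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "object",
            "required": ["id", "properties"],
            "properties": {
              "id": {"type": "string", "minLength": 1},
              "properties": {
                "type": "object",
                "additionalProperties": {"type": "string"}
              },
              "extras": {"type": "array", "items": {"type": "string"}},
              "typings": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["allele_assignment"],
                  "properties": {
                    "gene_family": {"type": "string"},
                    "allele_assignment": {
                      "type": "object",
                      "required": ["allele_db", "allele_version", "date", "glstring"],
                      "properties": {
                        "allele_db": {"type": "string"},
                        "allele_version": {"type": "string"},
                        "date": {"type": "string"},
                        "glstring": {"type": "string"}
                      }
                    },
                    "typing_method": {
                      "type": ["object", "null"],
                      "required": ["description"],
                      "properties": {
                        "description": {"type": "string"},
                        "platform": {"type": "string"},
                        "exons_targeted": {"type": "array", "items": {"type": "integer"}},
                        "software": {"type": "string"},
                        "software_version": {"type": "string"}
                      }
                    },
                    "consensus_sequence": {"type": ["string", "null"]},
                    "extras": {"type": "array", "items": {"type": "string"}}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
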