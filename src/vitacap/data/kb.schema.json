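{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "vitacap knowledge-base config",
  "description": "Vitamin biosynthesis knowledge base: functional roles (KO groups performing one reaction step), pathway variants (alternative routes with their indispensable roles), and cobalamin utilization gene lists. KO tokens are either KEGG ids (K#####) or curated gene-symbol aliases.",
  "type": "object",
  "required": ["version", "roles", "variants", "cobalamin_utilization"],
  "properties": {
    "version": {"type": "string"},
    "roles": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["role_id", "vitamin", "ko_ids"],
        "properties": {
          "role_id": {"type": "string", "minLength": 1},
          "vitamin": {"enum": ["THI", "RIB", "NIA", "PAN", "PYR", "BIO", "FOL", "COB", "MEN"]},
          "ko_ids": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "pattern": "^(K[0-9]{5}|[A-Za-z][A-Za-z0-9_.\\-]*)$"}
          },
          "label": {"type": "string"}
        }
      }
    },
    "variants": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variant_id", "vitamin", "role_ids", "indispensable_role_ids"],
        "properties": {
          "variant_id": {"type": "string", "minLength": 1},
          "vitamin": {"enum": ["THI", "RIB", "NIA", "PAN", "PYR", "BIO", "FOL", "COB", "MEN"]},
          "role_ids": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "indispensable_role_ids": {"type": "array", "minItems": 1, "items": {"type": "string"}},
          "segment_tag": {"type": ["string", "null"]}
        }
      }
    },
    "cobalamin_utilization": {
      "type": "object",
      "required": ["transporter_roles", "dependent_enzyme_roles"],
      "properties": {
        "transporter_roles": {
          "type": "object",
          "minProperties": 1,
          "additionalProperties": {"type": "array", "minItems": 1, "items": {"type": "string"}}
        },
        "dependent_enzyme_roles": {
          "type": "object",
          "minProperties": 1,
          "additionalProperties": {"type": "array", "minItems": 1, "items": {"type": "string"}}
        }
      }
    }
  }
}
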