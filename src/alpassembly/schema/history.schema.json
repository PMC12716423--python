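{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Mapped joint range-biome history file",
  "description": "Replicate joint biogeographic histories: per-branch piecewise states plus typed, timed events. Additional properties are allowed everywhere and round-trip untouched, so the format is extensible.",
  "type": "object",
  "required": ["format_version", "histories"],
  "properties": {
    "format_version": {"type": "string", "const": "1.0"},
    "n_histories": {"type": "integer", "minimum": 0},
    "histories": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["branches"],
        "properties": {
          "branches": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["branch_index", "parent_node", "child_node",
                           "start_age", "end_age", "start_state",
                           "end_state", "events"],
              "properties": {
                "branch_index": {"type": "integer", "minimum": 0},
                "parent_node": {"type": "integer", "minimum": -1},
                "child_node": {"type": "integer", "minimum": 0},
                "start_age": {"type": "number",
                              "description": "rootward end, Ma"},
                "end_age": {"type": "number",
                            "description": "tipward end, Ma"},
                "start_state": {"type": "integer", "minimum": 0,
                                "description": "canonical state index"},
                "end_state": {"type": "integer", "minimum": 0},
                "label": {"type": "string",
                          "description": "tip label, when terminal"},
                "events": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["age", "kind", "from_state", "to_states",
                                 "state_changed"],
                    "properties": {
                      "age": {"type": "number"},
                      "kind": {"enum": ["ANAGENETIC", "CLADOGENETIC_NODE",
                                        "CLADOGENETIC_HIDDEN"]},
                      "move_class": {
                        "type": ["string", "null"],
                        "description": "RANGE_EXPANSION | RANGE_CONTRACTION | BIOME_SHIFT | EXTINCTION for anagenetic events; WITHIN_REGION | BETWEEN_REGION for cladogenetic events"
                      },
                      "from_state": {"type": "integer", "minimum": 0},
                      "to_states": {
                        "type": "array",
                        "items": {"type": "integer", "minimum": 0},
                        "minItems": 1,
                        "maxItems": 2,
                        "description": "one state for anagenetic and hidden events, the ordered daughter pair for node events"
                      },
                      "state_changed": {"type": "boolean"}
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
}
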