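{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "migrec model configuration",
  "description": "A migration-recombination model. Sites are 1-based; probability tables use the lexicographic linear order over sites ascending, letters in declared alphabet order. Probabilities may be JSON numbers or 'p/q' fraction strings for exact-rational work.",
  "type": "object",
  "required": ["n", "demes", "recombination", "migration"],
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "seed": {"type": "integer"},
    "n": {"type": "integer", "minimum": 1, "description": "number of sequence sites"},
    "alphabets": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "string"}, "minItems": 1},
      "description": "one letter list per site; defaults to binary '0'/'1'"
    },
    "demes": {
      "type": "array",
      "items": {"type": "string"},
      "minItems": 1,
      "uniqueItems": true,
      "description": "ordered deme names; matrix indices follow this order"
    },
    "recombination": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["partition", "prob"],
        "properties": {
          "partition": {
            "type": "array",
            "items": {"type": "array", "items": {"type": "integer", "minimum": 1}},
            "description": "sorted list of sorted 1-based site lists, e.g. [[1,2],[3,4]]"
          },
          "prob": {"type": ["number", "string"]}
        }
      },
      "description": "sparse support of r; probabilities must sum to 1"
    },
    "migration": {
      "type": "object",
      "oneOf": [
        {"required": ["backward"]},
        {"required": ["forward", "sizes"]}
      ],
      "properties": {
        "backward": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}},
        "forward": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}},
        "sizes": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}}
      }
    },
    "initial": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": ["number", "string"]}},
      "description": "per-deme probability table over the product type space, flattened in the lexicographic linear order"
    },
    "rates": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["partition", "rate"],
        "properties": {
          "partition": {"type": "array", "items": {"type": "array", "items": {"type": "integer"}}},
          "rate": {"type": "number", "minimum": 0}
        }
      },
      "description": "continuous-time recombination rates (one-block partition is a no-op)"
    },
    "generator": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "number"}},
      "description": "continuous-time migration generator over demes: nonnegative off-diagonals, zero row sums"
    }
  }
}
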