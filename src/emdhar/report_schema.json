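{
  "$defs": {
    "PerClassMetrics": {
      "properties": {
        "precision": {
          "maximum": 1,
          "minimum": 0,
          "title": "Precision",
          "type": "number"
        },
        "recall": {
          "maximum": 1,
          "minimum": 0,
          "title": "Recall",
          "type": "number"
        },
        "f1": {
          "maximum": 1,
          "minimum": 0,
          "title": "F1",
          "type": "number"
        }
      },
      "required": [
        "precision",
        "recall",
        "f1"
      ],
      "title": "PerClassMetrics",
      "type": "object"
    }
  },
  "description": "Schema for the evaluation report JSON (shipped as report_schema.json).",
  "properties": {
    "config": {
      "additionalProperties": true,
      "title": "Config",
      "type": "object"
    },
    "accuracy": {
      "maximum": 1,
      "minimum": 0,
      "title": "Accuracy",
      "type": "number"
    },
    "macro_f1": {
      "maximum": 1,
      "minimum": 0,
      "title": "Macro F1",
      "type": "number"
    },
    "labels": {
      "items": {
        "type": "string"
      },
      "title": "Labels",
      "type": "array"
    },
    "confusion": {
      "items": {
        "items": {
          "type": "integer"
        },
        "type": "array"
      },
      "title": "Confusion",
      "type": "array"
    },
    "per_class": {
      "additionalProperties": {
        "$ref": "#/$defs/PerClassMetrics"
      },
      "title": "Per Class",
      "type": "object"
    }
  },
  "required": [
    "config",
    "accuracy",
    "macro_f1",
    "labels",
    "confusion",
    "per_class"
  ],
  "title": "Report",
  "type": "object"
}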