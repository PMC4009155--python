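{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spikefield CLI metrics",
  "description": "Machine-readable metrics emitted by the spikefield subcommands.",
  "type": "object",
  "properties": {
    "nmse": {
      "type": "array",
      "items": {"type": "number", "minimum": 0},
      "description": "Per-output-channel normalized mean squared error."
    },
    "train_nmse": {
      "type": "array",
      "items": {"type": "number", "minimum": 0}
    },
    "dictionary_size": {"type": "integer", "minimum": 0},
    "epoch_mse": {"type": "array", "items": {"type": "number", "minimum": 0}},
    "n_pulses": {"type": "integer", "minimum": 0},
    "mean_abs_filtered_error": {
      "type": "array",
      "items": {"type": "number", "minimum": 0},
      "description": "Per-epoch mean absolute filtered error (closed loop only)."
    },
    "seed": {"type": "integer"}
  },
  "additionalProperties": true
}
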