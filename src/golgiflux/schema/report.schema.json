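{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/golgiflux/report.schema.json",
  "title": "golgiflux run report",
  "type": "object",
  "required": [
    "scenario",
    "parameters",
    "species",
    "converged",
    "n_periods_used",
    "residual",
    "mass_balance_defect",
    "summaries"
  ],
  "properties": {
    "scenario": {"type": ["string", "null"]},
    "parameters": {
      "type": "object",
      "required": [
        "n_cisternae", "period", "omega", "n_sites", "T_ER",
        "topology", "boundary", "er_access", "linear_loading",
        "dt", "tol", "max_periods"
      ],
      "properties": {
        "n_cisternae": {"type": "integer", "minimum": 2},
        "period": {"type": "number", "exclusiveMinimum": 0},
        "omega": {"type": "number", "minimum": 0},
        "n_sites": {"type": "number", "exclusiveMinimum": 0},
        "T_ER": {"type": "number", "minimum": 0},
        "topology": {"enum": ["local", "unrestricted"]},
        "boundary": {"enum": ["open", "closed"]},
        "er_access": {"enum": ["first_cisterna_only", "all_cisternae", "none"]},
        "linear_loading": {"type": "boolean"},
        "dt": {"type": "number", "exclusiveMinimum": 0},
        "tol": {"type": "number", "exclusiveMinimum": 0},
        "max_periods": {"type": "integer", "minimum": 1}
      },
      "additionalProperties": false
    },
    "species": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "role", "K", "kappa", "C_init", "site_group"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "role": {
            "enum": [
              "t_snare_alpha", "v_snare_alpha", "t_snare_beta",
              "v_snare_beta", "er_v_snare", "passive_cargo"
            ]
          },
          "K": {"type": "number", "exclusiveMinimum": 0},
          "kappa": {"type": "number", "minimum": 0},
          "C_init": {"type": "number", "minimum": 0},
          "site_group": {"type": ["string", "null"]}
        },
        "additionalProperties": false
      }
    },
    "converged": {"type": "boolean"},
    "n_periods_used": {"type": "integer", "minimum": 1},
    "residual": {"type": "number", "minimum": 0},
    "mass_balance_defect": {"type": "number", "minimum": 0},
    "summaries": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "name", "argmax_cisterna", "peak_value", "total",
          "er_fraction", "monotonicity"
        ],
        "properties": {
          "name": {"type": "string"},
          "argmax_cisterna": {"type": "integer", "minimum": 1},
          "peak_value": {"type": "number", "minimum": 0},
          "total": {"type": "number", "minimum": 0},
          "er_fraction": {"type": "number", "minimum": 0, "maximum": 1},
          "monotonicity": {
            "enum": ["increasing", "decreasing", "unimodal", "constant", "other"]
          },
          "fitted_exponent": {"type": ["number", "null"]},
          "fit_r_squared": {"type": ["number", "null"]}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
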