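{
  "type": "object",
  "required_properties": {
    "config": {"type": "object", "required_properties": {}},
    "water_fit": {
      "type": "object",
      "required_properties": {
        "delta_eps_slow": {"type": "number"},
        "delta_eps_fast": {"type": "number"},
        "residual_rms": {"type": "number"}
      }
    },
    "hydration": {"type": "object", "required_properties": {}},
    "hydration_ternary": {"type": "object", "required_properties": {}},
    "normalized_rates": {"type": "object", "required_properties": {}},
    "correlation": {
      "type": "object",
      "required_properties": {
        "binary": {
          "type": "object",
          "required_properties": {
            "slope": {"type": "number"},
            "intercept": {"type": "number"},
            "r_squared": {"type": "number"}
          }
        }
      }
    }
  }
}
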