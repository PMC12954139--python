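{
  "coefficients": {
    "a": 2.7895,
    "b": 0.0326,
    "x": 0.0526,
    "y": 2.1659,
    "label": "published reference (EMINCA subgroup A)"
  },
  "threshold": {
    "level": 0.975,
    "cutoff": 1.144,
    "n_source": 857,
    "quantile_rule": "published",
    "label": "EMINCA subgroup A"
  },
  "reference_adjusted_r2": 0.6634
}
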