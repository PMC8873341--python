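{
  "description": "Summary statistics as printed in the published study the reference tables come from; used only for side-by-side display, never as computed output.",
  "control_means": {"10": 51.42, "20": 63.72, "30": 73.78, "40": 82.76, "50": 90.43, "60": 94.52},
  "baseline_means": {"10": 52.14, "20": 63.96, "30": 64.89, "40": 66.13, "50": 67.83, "60": 68.95},
  "t_value": 17.8723,
  "df": 9,
  "p_value": 2.443e-08,
  "mean_difference": 25.58,
  "control_max": 97.83
}
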