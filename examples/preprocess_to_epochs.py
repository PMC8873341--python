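"""From raw optical density to labeled training examples.

Runs the preprocessing chain on one simulated subject: invert the modified
Beer-Lambert law to hemoglobin concentrations, low-pass at 0.2 Hz, and cut
10 s windows (step 5 s) from every labeled segment.
"""

import numpy as np

from fnirs_transfer import lowpass_filter, make_cohort, mbll_invert, segment_epochs

rec = make_cohort(n_subjects=1, master_seed=3)[0]
hemo = mbll_invert(rec)
print(f"after MBLL inversion: {hemo.data.shape} (channels x [HbO, HbR] x samples)")
print(f"  HbO range: {hemo.data[:, 0].min():.2f} .. {hemo.data[:, 0].max():.2f} uM")

filtered = lowpass_filter(hemo, cutoff_hz=0.2)
hf_power_before = np.var(np.diff(hemo.data[0, 0]))
hf_power_after = np.var(np.diff(filtered.data[0, 0]))
print(f"sample-to-sample power before/after 0.2 Hz low-pass: "
      f"{hf_power_before:.2e} / {hf_power_after:.2e}")

epochs = segment_epochs(filtered, window_s=10.0, step_s=5.0, class_mode="3class")
print(f"epochs: {epochs.X.shape} (examples x channels x chromophores x samples)")
print("labels:", {c: int(n) for c, n in zip(*np.unique(epochs.y, return_counts=True))},
      "->", epochs.label_names())
print("series groups per subject:", len(set(epochs.groups)))
# 9 series x 7 windows = 63 examples, 21 per workload class; the filter
# strips cardiac/respiratory power (orders of magnitude in the diff
# variance) while the slow evoked response survives.
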