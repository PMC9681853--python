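"""Background-subtracted, tubulin-normalized spindle intensity quantification.

Computes the normalized intensity of a post-translational-modification
channel over the tubulin channel for ROI-level measurements,
(raw_x - area*noise_x) / (raw_tub - area*noise_tub), and recovers planted
group ratios from a synthetic two-group experiment.
"""

import pancscreen as ps

roi = ps.ROIMeasurement(
    raw_intensity_x=1000.0, raw_intensity_tub=2000.0,
    area=100.0, noise_x_mean=2.0, noise_tub_mean=4.0, roi_id="demo",
)
print(f"single ROI normalized intensity = {ps.normalized_intensity(roi):.3f}")

measurements, labels = ps.simulate_roi_measurements(
    {"control": 0.8, "knockdown": 0.5}, n_per_group=50, seed=7
)
table, p = ps.batch_normalize(measurements, labels, compare=True)
print(table.to_string(index=False))
print(f"Wilcoxon p (control vs knockdown) = {p:.2e}")
print("-> group means recover the planted 0.8 and 0.5 intensity ratios; the")
print("   ratio is invariant to channel gain and constant background.")
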