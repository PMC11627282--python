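"""Work with published ten-position group means as contours.

The ten-position profile of a cohort (group means at x = -8..+10 mm,
step 2) defines a piecewise-linear contour in its own right; running
peak detection on it locates the group-mean marginal peak. Equal-n
pooling combines two 16-patient surgical arms into whole-cohort means.
"""

from lidcontour import pooled_mean, polyline_peak, polyline_through_profile, profile_from_pairs

# External-levator-advancement arm of a unilateral-ptosis study:
# group means (mm) for the ptotic lid before/after repair and the fellow lid.
rows = {
    "preoperative ": [0.08, 0.75, 1.20, 1.40, 1.46, 1.29, 0.90, 0.39, -0.24, -1.14],
    "postoperative": [0.23, 1.23, 1.90, 2.34, 2.43, 2.19, 1.72, 0.93, 0.02, -1.0],
    "fellow eyelid": [0.61, 1.64, 2.31, 2.82, 2.88, 2.78, 2.51, 1.90, 1.06, -0.17],
}

for name, heights in rows.items():
    xs, ys = polyline_through_profile(profile_from_pairs(heights))
    pk = polyline_peak(xs, ys)
    print(f"{name}: peak at x = {pk.x_mm:+.2f} mm, height = {pk.y_mm:.2f} mm")

# Pooling the two equal-sized arms (second arm: Muller's muscle resection)
print("pooled baseline MRD1:", pooled_mean([1.46, 1.12], [16, 16]), "mm")
print("pooled fellow  MRD1:", pooled_mean([2.88, 2.58], [16, 16]), "mm")

# On these group-mean contours the peak falls at the pupil center (x = 0),
# so the peak height equals the group-mean MRD1.
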