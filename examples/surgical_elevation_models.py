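"""Compare the two surgical elevation models on one ptotic contour.

A uniform elevation (the "dome tent" pattern attributed to Muller's
muscle conjunctival resection) raises every margin point equally; a
center-weighted Gaussian elevation (the "bell tent" pattern attributed
to external levator advancement, supported by one central suture) fades
toward the canthi and drags a nasally displaced peak temporally.
"""

import numpy as np

from lidcontour import ContourParams, GRID_LABELS, GRID_X, SurgeryModel, apply_surgery, make_contour

pre = make_contour(ContourParams(peak_x=-1.2, peak_y=1.6))
uniform = apply_surgery(pre, SurgeryModel(kind="uniform", effect_mm=1.1))
tapered = apply_surgery(pre, SurgeryModel(kind="center_weighted", effect_mm=1.0,
                                          taper_width_mm=5.0, center_x=0.0))

print(f"{'pos':>5} {'pre':>6} {'uniform':>8} {'tapered':>8}")
for lab, x in zip(GRID_LABELS, GRID_X):
    print(f"{lab:>5} {pre.height(x):6.2f} {uniform.height(x):8.2f} {tapered.height(x):8.2f}")

print(f"\npre     peak: ({pre.peak.x_mm:+.2f}, {pre.peak.y_mm:.2f}) mm")
print(f"uniform peak: ({uniform.peak.x_mm:+.2f}, {uniform.peak.y_mm:.2f}) mm")
print(f"tapered peak: ({tapered.peak.x_mm:+.2f}, {tapered.peak.y_mm:.2f}) mm")

# Uniform elevation preserves the peak position; the center-weighted model
# gains the same central height but much less toward N8/T10, and shifts the
# peak temporally toward the suture point.
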