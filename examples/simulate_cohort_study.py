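"""Simulate a two-arm unilateral-ptosis study and run the full pipeline.

Generates 16 patients per arm (center-weighted elevation for the
levator-advancement-like arm, uniform for the Muller's-muscle-like arm),
writes annotation JSONs plus a manifest, measures every photo, and emits
per-arm cohort tables with paired per-position t-tests.
"""

import tempfile
from pathlib import Path

import pandas as pd

from lidcontour import StudyConfig, run_simulation

out = Path(tempfile.mkdtemp()) / "study"
report = run_simulation(StudyConfig(manifest=out / "m.csv", out_dir=out, seed=7,
                                    n_patients_per_arm=16))

print("arms:", report.arms, "triplets per arm:", report.n_triplets)
for arm in report.arms:
    table = pd.read_csv(report.tables[f"cohort_{arm}"], index_col=0)
    sig = table.loc["sig_change"].astype(bool)
    print(f"\n{arm}: positions with significant elevation (p < 0.05):",
          ", ".join(sig.index[sig]) or "none")
    print(table.loc[["mean_pre", "mean_post", "mean_fellow", "p_change"]]
          .astype(float).round(3).to_string())

# The uniform arm elevates strongly and evenly at all ten positions. In the
# center-weighted arm the evidence for elevation weakens toward the canthi
# (largest p-values at N8/T8/T10), the qualitative contrast between the two
# repair techniques; which edge positions cross the 0.05 line varies seed
# to seed because the tapered effect there is small relative to noise.
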