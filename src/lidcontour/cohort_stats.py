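"""Cohort-level statistics for ptosis-repair outcome comparisons.

The study design is within-patient: each patient contributes a ptotic
eyelid measured before and ~6 months after surgery and a non-ptotic
fellow eyelid as the symmetry reference. Per grid position (and for the
peak-point coordinates) two paired two-sided Student t-tests are run:

* **change**: preoperative vs. postoperative ptotic eyelid;
* **symmetry**: postoperative ptotic eyelid vs. fellow eyelid.

Missing heights (grid positions outside a traced margin) are handled by
pairwise deletion: each position's test uses only patients with both
members of the pair present. Significance is flagged at alpha = 0.05 by
default with no multiple-testing correction across the 10 positions;
Holm correction is available via ``correction="holm"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contour_metrics import GRID_LABELS, ContourProfile, PeakPoint

#: Smallest reportable p-value when the paired differences have zero
#: variance but a nonzero mean (the t statistic is unbounded).
P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class PatientTriplet:
    """One patient's measurements: ptotic eyelid pre/post plus fellow eyelid."""

    patient_id: str
    profile_pre: ContourProfile
    profile_post: ContourProfile
    profile_fellow: ContourProfile
    peak_pre: PeakPoint
    peak_post: PeakPoint
    peak_fellow: PeakPoint
    arm: Literal["ELA", "MMCR"]


@dataclass(frozen=True)
class PairedTResult:
    """Two-sided paired Student t-test on within-patient differences."""

    t: float
    p: float
    n: int
    df: int
    mean_diff: float
    underflow: bool = False  # zero-variance nonzero differences: p below machine floor


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test of ``a`` vs ``b`` with pairwise NaN deletion.

    Identical samples give t = 0, p = 1. If the differences are a
    nonzero constant (zero variance) the t statistic diverges; p is
    reported at the machine floor with ``underflow=True``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same length")
    ok = np.isfinite(a) & np.isfinite(b)
    d = a[ok] - b[ok]
    n = int(d.size)
    if n < 2:
        raise ValueError(f"paired t-test needs at least 2 complete pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, n=n, df=df, mean_diff=0.0)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(t=float(t), p=P_FLOOR, n=n, df=df, mean_diff=mean, underflow=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTResult(t=float(t), p=min(p, 1.0), n=n, df=df, mean_diff=mean)


def group_mean_profile(profiles: Sequence[ContourProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position arithmetic means over profiles, ignoring missing heights.

    Returns ``(means, n)``: the mean at each of the 10 positions (NaN
    where every profile is missing) and the count of non-missing values
    used per position.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    mat = np.vstack([p.values for p in profiles])
    finite = np.isfinite(mat)
    n = finite.sum(axis=0)
    sums = np.where(finite, mat, 0.0).sum(axis=0)
    means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return means, n


def _adjust(pvals: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return pvals
    if correction == "holm":
        ok = np.isfinite(pvals)
        out = np.full_like(pvals, np.nan)
        p = pvals[ok]
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        out[ok] = adj
        return out
    raise ValueError("correction must be 'none' or 'holm'")


def contour_change_table(
    cohort: Sequence[PatientTriplet],
    arm: Optional[str] = None,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Per-position cohort table: group means, change and symmetry tests.

    Columns are the 10 grid positions; rows are the pre/post/fellow
    group means, the two p-values, the n used by each test, and boolean
    significance flags at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if arm is not None:
        cohort = [t for t in cohort if t.arm == arm]
    if len(cohort) == 0:
        raise ValueError("empty cohort")

    pre = np.vstack([t.profile_pre.values for t in cohort])
    post = np.vstack([t.profile_post.values for t in cohort])
    fellow = np.vstack([t.profile_fellow.values for t in cohort])

    mean_pre, _ = group_mean_profile([t.profile_pre for t in cohort])
    mean_post, _ = group_mean_profile([t.profile_post for t in cohort])
    mean_fellow, _ = group_mean_profile([t.profile_fellow for t in cohort])

    p_change = np.full(10, np.nan)
    p_symmetry = np.full(10, np.nan)
    n_change = np.zeros(10, dtype=int)
    n_symmetry = np.zeros(10, dtype=int)
    for j in range(10):
        try:
            r = paired_t(post[:, j], pre[:, j])
            p_change[j], n_change[j] = r.p, r.n
        except ValueError:
            pass
        try:
            r = paired_t(post[:, j], fellow[:, j])
            p_symmetry[j], n_symmetry[j] = r.p, r.n
        except ValueError:
            pass

    p_change = _adjust(p_change, correction)
    p_symmetry = _adjust(p_symmetry, correction)

    table = pd.DataFrame(
        {
            "mean_pre": mean_pre,
            "mean_post": mean_post,
            "mean_fellow": mean_fellow,
            "p_change": p_change,
            "p_symmetry": p_symmetry,
            "n_change": n_change,
            "n_symmetry": n_symmetry,
            "sig_change": p_change < alpha,
            "sig_symmetry": p_symmetry < alpha,
        },
        index=list(GRID_LABELS),
    ).T
    table.columns.name = "position"
    return table


def peak_shift_summary(
    cohort: Sequence[PatientTriplet], alpha: float = 0.05
) -> dict[str, dict[str, float]]:
    """Group means and paired tests for the peak-point coordinates.

    For each coordinate (x, y): means over pre/post/fellow, the
    pre-vs-post change test and the post-vs-fellow symmetry test.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 triplets")
    out: dict[str, dict[str, float]] = {}
    for coord in ("x", "y"):
        attr = f"{coord}_mm"
        pre = np.array([getattr(t.peak_pre, attr) for t in cohort])
        post = np.array([getattr(t.peak_post, attr) for t in cohort])
        fellow = np.array([getattr(t.peak_fellow, attr) for t in cohort])
        change = paired_t(post, pre)
        symmetry = paired_t(post, fellow)
        out[coord] = {
            "mean_pre": float(pre.mean()),
            "mean_post": float(post.mean()),
            "mean_fellow": float(fellow.mean()),
            "p_change": change.p,
            "p_symmetry": symmetry.p,
            "sig_change": bool(change.p < alpha),
            "sig_symmetry": bool(symmetry.p < alpha),
            "n": change.n,
        }
    return out


def pooled_mean(group_means: Sequence[float], group_ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of per-group means (pools study arms)."""
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if means.size == 0 or means.shape != ns.shape:
        raise ValueError("group_means and group_ns must be equal-length and non-empty")
    if np.any(ns <= 0):
        raise ValueError("group sizes must be positive")
    return float(np.sum(means * ns) / np.sum(ns))
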