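"""GLCM-size sensitivity sweep and between-class feature statistics.

Runs feature extraction over the ten standard GLCM sizes, screens every
feature for between-tumor-type differences with one-way ANOVA under a
Bonferroni-corrected threshold (alpha / m over the 99 class-by-feature
hypotheses), and ranks features by how strongly their cohort means move
with GLCM size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import DEFAULT_LEVELS, FEATURE_NAMES, extract_features_table
from .imaging import ValidationError

__all__ = [
    "AnovaResult",
    "sweep_glcm_sizes",
    "anova_by_type",
    "anova_table",
    "bonferroni_threshold",
    "size_dependence_report",
]


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA for one feature at one GLCM size."""

    feature: str
    n_levels: Optional[int]
    f_statistic: float
    p_value: float
    significant: bool
    threshold: float
    note: str = ""


def sweep_glcm_sizes(
    scans: Iterable,
    regions: Sequence[str] = ("whole",),
    levels: Sequence[int] = DEFAULT_LEVELS,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Feature extraction for every (scan, region, GLCM size) combination.

    Returns a long-format table (scan_id, animal_id, class, day, region,
    n_levels, feature, value); combinations whose region is absent or
    degenerate appear with NaN values and a ``failure`` reason rather than
    being dropped silently.
    """
    levels = list(levels)
    if not levels:
        raise ValidationError("levels list is empty")
    wide = extract_features_table(scans, regions=regions, levels=levels, seed=seed)
    if wide.empty:
        raise ValidationError("no scans supplied to the sweep")
    meta_cols = ["scan_id", "animal_id", "class", "day", "region", "n_levels", "failure"]
    long = wide.melt(
        id_vars=meta_cols, value_vars=list(FEATURE_NAMES),
        var_name="feature", value_name="value",
    )
    return long


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def anova_by_type(
    groups: Sequence[Sequence[float]],
    feature: str = "",
    n_levels: Optional[int] = None,
    alpha: float = 0.05,
    m: int = 99,
) -> AnovaResult:
    """One-way fixed-effects F test of a feature across tumor classes.

    The significance flag compares the raw p-value against the Bonferroni
    threshold ``alpha / m``.  When every group has zero internal variance
    but the means differ, the F statistic is infinite and the p-value is
    reported as the smallest positive float, with a degeneracy note.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least two observations")
    thresh = bonferroni_threshold(alpha, m)
    note = ""
    grand = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means_differ = np.ptp([a.mean() for a in arrays]) > 0
    if ss_within == 0 and means_differ:
        f_stat = float("inf")
        p = float(np.nextafter(0, 1))
        note = "zero within-group variance with unequal means"
    elif ss_within == 0 and not means_differ:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*arrays)
        f_stat, p = float(f_stat), float(p)
        if np.isnan(f_stat):  # identical constant groups
            f_stat, p = 0.0, 1.0
    return AnovaResult(
        feature=feature, n_levels=n_levels, f_statistic=f_stat, p_value=p,
        significant=bool(p < thresh), threshold=thresh, note=note,
    )


def anova_table(
    sweep: pd.DataFrame,
    alpha: float = 0.05,
    m: int = 99,
) -> pd.DataFrame:
    """Per-(feature, GLCM size) ANOVA across classes from a sweep table.

    Reports the raw p-value, the Bonferroni flag at ``alpha / m`` and the
    equivalent adjusted p-value ``min(p * m, 1)``.  Feature/size cells with
    fewer than two observations in some class are skipped.
    """
    rows = []
    for (feat, n), sub in sweep.dropna(subset=["value"]).groupby(
            ["feature", "n_levels"], sort=False):
        groups = [g["value"].to_numpy() for _, g in sub.groupby("class")]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        r = anova_by_type(groups, feature=feat, n_levels=int(n), alpha=alpha, m=m)
        rows.append({
            "feature": feat, "n_levels": int(n), "F": r.f_statistic,
            "p": r.p_value, "p_adjusted": min(r.p_value * m, 1.0),
            "significant": r.significant, "threshold": r.threshold,
            "note": r.note,
        })
    return pd.DataFrame(rows)


def size_dependence_report(sweep: pd.DataFrame) -> pd.DataFrame:
    """Rank features by how much their cohort means move with GLCM size.

    For each (region, feature), the per-size cohort means m_N are reduced
    to a relative range ``(max - min) / max(|mean|, eps)`` — the
    dependence statistic — plus a Spearman rank correlation of m_N against
    N as a monotonic-trend test.  Features are returned sorted by
    descending dependence.
    """
    usable = sweep.dropna(subset=["value"])
    n_sizes = usable["n_levels"].nunique()
    if n_sizes < 3:
        raise ValidationError("size-dependence needs >= 3 GLCM sizes in the sweep")
    rows = []
    for (region, feat), sub in usable.groupby(["region", "feature"], sort=False):
        means = sub.groupby("n_levels")["value"].mean().sort_index()
        if len(means) < 3:
            continue
        scale = max(abs(float(means.mean())), np.finfo(float).eps)
        dependence = float((means.max() - means.min()) / scale)
        if means.nunique() == 1:
            rho, p = 0.0, 1.0
            dependence = 0.0
        else:
            rho, p = sps.spearmanr(means.index.to_numpy(), means.to_numpy())
        rows.append({
            "region": region, "feature": feat, "dependence": dependence,
            "spearman_rho": float(rho), "trend_p": float(p),
            "n_sizes": len(means),
        })
    out = pd.DataFrame(rows).sort_values("dependence", ascending=False)
    return out.reset_index(drop=True)
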