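"""Gray-level co-occurrence texture features.

The pipeline quantizes intensities into ``N`` equal-width bins over the
whole volume, counts co-occurring level pairs at pixel distance 1 along the
four in-plane directions (0°, 45°, 90°, 135°, symmetric), normalizes and
averages the four matrices, and — for the whole-tumor region — averages the
per-slice matrices before computing features.  33 named features are
emitted per region: 10 first-order statistics of the raw in-ROI intensity
histogram and 23 second-order statistics of the normalized GLCM, following
the Haralick / Soh / Clausi definitions with their IBSI reference codes.

Entropy-type features use base-2 logarithms with the convention
``0 * log 0 = 0``.  First-order skewness and kurtosis are population
(biased) moments; kurtosis is non-excess (a Gaussian scores 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import (
    ImageVolume,
    ROIMask,
    RegionSelection,
    ValidationError,
    locate_region_slices,
    region_for_kind,
    slice_areas,
)

__all__ = [
    "GLCM_DIRECTIONS",
    "DEFAULT_LEVELS",
    "FEATURE_REGISTRY",
    "FIRST_ORDER_NAMES",
    "SECOND_ORDER_NAMES",
    "FEATURE_NAMES",
    "GLCMatrix",
    "FeatureVector",
    "quantize_intensities",
    "compute_glcm",
    "aggregate_glcm",
    "whole_tumor_glcm",
    "first_order_features",
    "second_order_features",
    "extract_feature_vector",
    "extract_features_table",
]

#: (row, col) steps for the four offsets at distance 1, image convention
#: (row axis points down): 0° → right, 45° → up-right, 90° → up, 135° → up-left.
GLCM_DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

#: The ten GLCM sizes of the sensitivity sweep.
DEFAULT_LEVELS: tuple[int, ...] = (8, 16, 24, 32, 48, 64, 98, 128, 256, 512)

# name -> (order, IBSI reference code)
FEATURE_REGISTRY: dict[str, tuple[str, str]] = {
    # first order: statistics of the raw in-ROI intensity distribution
    "mean_intensity": ("first", "Q4LE"),
    "median_intensity": ("first", "Y12H"),
    "intensity_variance": ("first", "ECT3"),
    "intensity_skewness": ("first", "KE2A"),
    "intensity_kurtosis": ("first", "IPH6"),
    "intensity_minimum": ("first", "1GSF"),
    "intensity_maximum": ("first", "84IY"),
    "intensity_range": ("first", "2OJQ"),
    "intensity_energy": ("first", "N8CA"),
    "intensity_entropy": ("first", "GXB7"),
    # second order: statistics of the normalized GLCM
    "autocorrelation": ("second", "QWB0"),
    "cluster_prominence": ("second", "AE86"),
    "cluster_shade": ("second", "7NFM"),
    "contrast": ("second", "ACUI"),
    "correlation": ("second", "NI2N"),
    "difference_average": ("second", "TF7R"),
    "difference_entropy": ("second", "NTRS"),
    "difference_variance": ("second", "D3YU"),
    "dissimilarity": ("second", "8S9J"),
    "joint_energy": ("second", "8ZQL"),
    "joint_entropy": ("second", "TU9B"),
    "inverse_difference": ("second", "IB1Z"),
    "inverse_difference_normalized": ("second", "NDRX"),
    "inverse_difference_moment": ("second", "WF0Z"),
    "inverse_difference_moment_normalized": ("second", "1QCO"),
    "inverse_variance": ("second", "E8JP"),
    "maximum_probability": ("second", "GYBY"),
    "sum_average": ("second", "ZGXS"),
    "sum_entropy": ("second", "P6QZ"),
    "sum_variance": ("second", "OEEB"),
    "sum_of_squares": ("second", "UR99"),
    "information_correlation_1": ("second", "R8DG"),
    "information_correlation_2": ("second", "JN9H"),
}

FIRST_ORDER_NAMES = tuple(k for k, (o, _) in FEATURE_REGISTRY.items() if o == "first")
SECOND_ORDER_NAMES = tuple(k for k, (o, _) in FEATURE_REGISTRY.items() if o == "second")
FEATURE_NAMES = tuple(FEATURE_REGISTRY)

_HIST_BINS = 256  # fixed bin count for the first-order intensity entropy


@dataclass
class GLCMatrix:
    """A gray-level co-occurrence matrix and its construction provenance."""

    values: np.ndarray
    n_levels: int
    normalized: bool = False
    offsets_averaged: bool = False
    distance: int = 1
    directions: tuple[int, ...] = ()
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_levels, self.n_levels):
            raise ValidationError("GLCM must be square n_levels x n_levels")


@dataclass
class FeatureVector:
    """33 named texture features plus extraction provenance."""

    features: dict[str, float]
    scan_id: Optional[str] = None
    region: Optional[str] = None
    n_levels: Optional[int] = None

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        extra = set(self.features) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValidationError(
                f"feature vector must carry exactly the registry's "
                f"{len(FEATURE_NAMES)} features (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )

    def __len__(self) -> int:
        return len(self.features)

    def to_series(self) -> pd.Series:
        s = pd.Series({k: self.features[k] for k in FEATURE_NAMES})
        s.name = self.scan_id
        return s


def quantize_intensities(voxels: np.ndarray | ImageVolume, n_levels: int) -> np.ndarray:
    """Bin intensities linearly into levels 1..N over the whole array.

    The bin width is ``(max - min) / N``; the maximum intensity is assigned
    level N.  A constant array maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValidationError("n_levels must be >= 2")
    if isinstance(voxels, ImageVolume):
        voxels = voxels.voxels
    x = np.asarray(voxels, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones(x.shape, dtype=np.int64)
    idx = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(idx, 1, n_levels)


def compute_glcm(
    indexed: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    direction: int,
    distance: int = 1,
) -> GLCMatrix:
    """Count symmetric level co-occurrences on one slice.

    A pair contributes only when both endpoints lie inside the mask.
    Symmetry is applied by adding the transpose, so the total count equals
    twice the number of ordered in-mask pairs along the offset.
    """
    if direction not in GLCM_DIRECTIONS:
        raise ValidationError(f"direction must be one of {sorted(GLCM_DIRECTIONS)}")
    if distance < 1:
        raise ValidationError("distance must be >= 1")
    indexed = np.asarray(indexed)
    mask = np.asarray(mask, dtype=bool)
    if indexed.shape != mask.shape or indexed.ndim != 2:
        raise ValidationError("indexed slice and mask must be equal-shape 2D arrays")
    if not mask.any():
        raise ValidationError("mask slice is empty")
    dr, dc = (d * distance for d in GLCM_DIRECTIONS[direction])
    rows, cols = indexed.shape
    r0 = slice(max(0, -dr), min(rows, rows - dr))
    c0 = slice(max(0, -dc), min(cols, cols - dc))
    r1 = slice(max(0, dr), min(rows, rows + dr))
    c1 = slice(max(0, dc), min(cols, cols + dc))
    a = indexed[r0, c0]
    b = indexed[r1, c1]
    ok = mask[r0, c0] & mask[r1, c1]
    P = np.zeros((n_levels, n_levels), dtype=float)
    if ok.any():
        np.add.at(P, (a[ok] - 1, b[ok] - 1), 1.0)
    P = P + P.T
    return GLCMatrix(
        P,
        n_levels,
        normalized=False,
        distance=distance,
        directions=(direction,),
        degenerate=not bool(P.sum()),
    )


def aggregate_glcm(glcms: Sequence[GLCMatrix]) -> GLCMatrix:
    """Normalize each directional matrix to sum 1, then average them.

    Degenerate (all-zero) directions are excluded from the average; the
    result is degenerate only when every input is.
    """
    if not glcms:
        raise ValidationError("no GLCMs to aggregate")
    n = glcms[0].n_levels
    if any(g.n_levels != n for g in glcms):
        raise ValidationError("GLCM sizes differ")
    live = [g for g in glcms if not g.degenerate]
    dirs = tuple(sorted({d for g in glcms for d in g.directions}))
    if not live:
        return GLCMatrix(
            np.zeros((n, n)), n, normalized=True, offsets_averaged=True,
            directions=dirs, degenerate=True,
        )
    acc = np.zeros((n, n))
    for g in live:
        acc += g.values / g.values.sum()
    return GLCMatrix(
        acc / len(live), n, normalized=True, offsets_averaged=True, directions=dirs
    )


def whole_tumor_glcm(slice_glcms: Sequence[GLCMatrix]) -> GLCMatrix:
    """Average normalized per-slice GLCMs into one whole-tumor matrix."""
    live = [g for g in slice_glcms if not g.degenerate]
    if not live:
        raise ValidationError("all slice GLCMs are degenerate")
    n = live[0].n_levels
    acc = np.zeros((n, n))
    for g in live:
        v = g.values
        acc += v / v.sum()
    return GLCMatrix(
        acc / len(live), n, normalized=True, offsets_averaged=True,
        directions=live[0].directions,
    )


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def first_order_features(sample: np.ndarray) -> dict[str, float]:
    """Moment and histogram statistics of raw in-ROI intensities.

    Population (biased) moments; kurtosis is non-excess.  A constant sample
    leaves skewness and kurtosis undefined (NaN) rather than silently zero.
    The intensity entropy uses a 256-bin histogram over the sample range.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 1:
        raise ValidationError("empty intensity sample")
    mu = float(x.mean())
    var = float(x.var())
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((x - mu) ** 3).mean() / sd**3)
        kurt = float(((x - mu) ** 4).mean() / var**2)
    else:
        skew = float("nan")
        kurt = float("nan")
    if x.max() > x.min():
        hist, _ = np.histogram(x, bins=_HIST_BINS, range=(x.min(), x.max()))
        ent = _entropy2(hist / hist.sum())
    else:
        ent = 0.0
    return {
        "mean_intensity": mu,
        "median_intensity": float(np.median(x)),
        "intensity_variance": var,
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_minimum": float(x.min()),
        "intensity_maximum": float(x.max()),
        "intensity_range": float(x.max() - x.min()),
        "intensity_energy": float((x**2).sum()),
        "intensity_entropy": ent,
    }


def second_order_features(glcm: GLCMatrix) -> dict[str, float]:
    """The 23 GLCM statistics of the registry, from a normalized matrix.

    A zero-variance matrix (all mass in one cell) leaves ``correlation``
    undefined (NaN); every other feature is still returned.  When the
    marginal entropies vanish the information measures of correlation are
    likewise NaN.
    """
    if glcm.degenerate:
        raise ValidationError("cannot compute features of a degenerate GLCM")
    p = np.asarray(glcm.values, dtype=float)
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValidationError("GLCM must be normalized (sum to 1)")
    n = glcm.n_levels
    i = np.arange(1, n + 1)
    px = p.sum(axis=1)  # marginal over rows
    py = p.sum(axis=0)
    mu_i = float(i @ px)
    mu_j = float(i @ py)
    var_i = float(((i - mu_i) ** 2) @ px)
    var_j = float(((i - mu_j) ** 2) @ py)

    ii = i[:, None]
    jj = i[None, :]
    diff = ii - jj
    absdiff = np.abs(diff)

    # cross moments
    auto = float((ii * jj * p).sum())
    contrast = float((diff**2 * p).sum())
    dissim = float((absdiff * p).sum())
    if var_i > 0 and var_j > 0:
        corr = (auto - mu_i * mu_j) / np.sqrt(var_i * var_j)
    else:
        corr = float("nan")
    cs_base = ii + jj - mu_i - mu_j
    shade = float((cs_base**3 * p).sum())
    prom = float((cs_base**4 * p).sum())
    ssq = float(((ii - mu_i) ** 2 * p).sum())

    # sum and difference distributions
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    k_dif = np.arange(0, n)
    p_dif = np.bincount(absdiff.ravel(), weights=p.ravel(), minlength=n)[:n]
    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_ent = _entropy2(p_sum)
    dif_avg = float(k_dif @ p_dif)
    dif_var = float(((k_dif - dif_avg) ** 2) @ p_dif)
    dif_ent = _entropy2(p_dif)

    # entropy family and information measures of correlation
    h_xy = _entropy2(p)
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxpy = np.outer(px, py)
    pos = pxpy > 0
    h_xy1 = float(-(p[pos] * np.log2(pxpy[pos])).sum())
    h_xy2 = _entropy2(pxpy)
    hmax = max(hx, hy)
    imc1 = (h_xy - h_xy1) / hmax if hmax > 0 else float("nan")
    arg = 1.0 - np.exp(-2.0 * np.log(2.0) * (h_xy2 - h_xy))
    imc2 = float(np.sqrt(max(arg, 0.0))) if hmax > 0 else float("nan")

    off = diff != 0
    inv_var = float((p[off] / diff[off] ** 2).sum())

    return {
        "autocorrelation": auto,
        "cluster_prominence": prom,
        "cluster_shade": shade,
        "contrast": contrast,
        "correlation": float(corr),
        "difference_average": dif_avg,
        "difference_entropy": dif_ent,
        "difference_variance": dif_var,
        "dissimilarity": dissim,
        "joint_energy": float((p**2).sum()),
        "joint_entropy": h_xy,
        "inverse_difference": float((p / (1.0 + absdiff)).sum()),
        "inverse_difference_normalized": float((p / (1.0 + absdiff / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "inverse_difference_moment_normalized": float((p / (1.0 + diff**2 / n**2)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": sum_ent,
        "sum_variance": sum_var,
        "sum_of_squares": ssq,
        "information_correlation_1": float(imc1),
        "information_correlation_2": imc2,
    }


def _slice_aggregated_glcm(
    indexed: np.ndarray, mask: np.ndarray, n_levels: int, distance: int = 1
) -> GLCMatrix:
    return aggregate_glcm(
        [compute_glcm(indexed, mask, n_levels, d, distance) for d in GLCM_DIRECTIONS]
    )


def extract_feature_vector(
    volume: ImageVolume,
    mask: ROIMask,
    region: RegionSelection | str,
    n_levels: int,
    seed: Optional[int] = None,
    side: str = "auto",
    indexed: Optional[np.ndarray] = None,
) -> FeatureVector:
    """Extract the 33-feature vector for one tumor region.

    Intensity binning spans the entire volume so that per-slice matrices
    share one gray-level scale.  Single-slice regions use that slice's
    offset-averaged GLCM and in-ROI pixels; the whole-tumor region averages
    the per-slice GLCMs and pools the in-mask pixels of all visible slices.

    ``indexed`` lets a caller reuse a precomputed ``quantize_intensities``
    result when sweeping many regions at one GLCM size.
    """
    if mask.shape != volume.shape:
        raise ValidationError("mask and volume shapes differ")
    if isinstance(region, str):
        region = region_for_kind(mask, region, seed=seed, side=side)
    if not region.available:
        raise ValidationError(f"region {region.kind!r} is absent for this tumor")
    if indexed is None:
        indexed = quantize_intensities(volume.voxels, n_levels)

    slice_glcms = []
    pixels = []
    for k in region.chosen_slice_indices:
        m = mask.voxels[k]
        if not m.any():
            raise ValidationError(f"selected slice {k} has no in-mask pixels")
        slice_glcms.append(_slice_aggregated_glcm(indexed[k], m, n_levels))
        pixels.append(np.asarray(volume.voxels[k])[m])
    live = [g for g in slice_glcms if not g.degenerate]
    if not live:
        raise ValidationError(
            f"degenerate GLCM for region {region.kind!r}: no co-occurring "
            f"in-mask pixel pairs on slices {region.chosen_slice_indices}"
        )
    glcm = whole_tumor_glcm(slice_glcms) if len(slice_glcms) > 1 else live[0]
    feats = first_order_features(np.concatenate(pixels))
    feats.update(second_order_features(glcm))
    return FeatureVector(
        feats, scan_id=volume.scan_id, region=region.kind, n_levels=n_levels
    )


def extract_features_table(
    scans: Iterable[tuple[ImageVolume, ROIMask]],
    regions: Sequence[str] = ("whole",),
    levels: Sequence[int] = (512,),
    seed: Optional[int] = None,
    side: str = "auto",
) -> pd.DataFrame:
    """Run extraction over scans × regions × GLCM sizes into a wide table.

    One row per combination; metadata columns (scan_id, animal_id, class,
    day, region, n_levels) then the 33 features.  Regions that are absent
    or degenerate for a scan are recorded with NaN features and a
    ``failure`` reason, mirroring the practice of dropping too-small tumors
    from single-slice analyses.
    """
    rows = []
    for volume, mask in scans:
        resolved: dict[str, RegionSelection] = {}
        try:
            resolved = locate_region_slices(mask, seed=seed, side=side)
        except ValidationError:
            pass
        indexed_cache = {n: quantize_intensities(volume.voxels, n) for n in levels}
        for region in regions:
            meta = {
                "scan_id": volume.scan_id,
                "animal_id": volume.animal_id,
                "class": volume.class_label,
                "day": volume.day_post_implant,
                "region": region,
            }
            for n in levels:
                row = dict(meta, n_levels=n, failure=None)
                try:
                    sel = (
                        region_for_kind(mask, "whole")
                        if region == "whole"
                        else resolved[region]
                    )
                    fv = extract_feature_vector(
                        volume, mask, sel, n, indexed=indexed_cache[n]
                    )
                    row.update(fv.features)
                except (ValidationError, KeyError) as exc:
                    row["failure"] = str(exc) or "region absent"
                    row.update({k: np.nan for k in FEATURE_NAMES})
                rows.append(row)
    return pd.DataFrame(rows)
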