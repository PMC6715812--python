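"""Synthetic tumor-imaging cohorts.

Generates T1-post-contrast-like phantom volumes for three tumor classes —
a mouse glioma, a human glioma and a human medulloblastoma — whose in-mask
texture is a correlated Gaussian random field, whose border sharpness
differs by class (well-defined glioma borders versus diffuse
medulloblastoma borders), and whose longitudinal volumes follow the
one-term exponential growth law V(t) = alpha * exp(beta * t) with
class-specific (alpha, beta) distributions.

Everything is a pure function of its arguments and seed; cohorts are lazy
(scan voxel data is regenerated deterministically on demand) so large
cohorts never need to be held in memory or on disk at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import (
    ImageVolume,
    ROIMask,
    SizingError,
    ValidationError,
    save_dicom_series,
    save_nifti,
)

__all__ = [
    "PhantomClassSpec",
    "CohortConfig",
    "GrowthSeries",
    "Cohort",
    "default_class_specs",
    "generate_phantom_volume",
    "generate_growth_series",
    "generate_cohort",
]

_BACKGROUND_MEAN = 100.0  # non-enhancing tissue intensity, arbitrary units


@dataclass(frozen=True)
class PhantomClassSpec:
    """Statistical description of one synthetic tumor class.

    ``texture_correlation_length`` (pixels) sets the in-plane smoothing of
    the intensity random field; ``border_softness`` (pixels) is the width
    of the edge blur between tumor and background.  ``alpha_*`` (mm^3) and
    ``beta_*`` (per day) parameterize the per-animal exponential growth
    draw.
    """

    class_label: str
    texture_correlation_length: float
    intensity_mean: float
    intensity_sd: float
    border_softness: float
    alpha_mean: float
    alpha_sd: float
    beta_mean: float
    beta_sd: float

    def __post_init__(self) -> None:
        if self.intensity_sd <= 0:
            raise ValidationError("intensity_sd must be > 0")
        if self.texture_correlation_length <= 0:
            raise ValidationError("texture_correlation_length must be > 0")
        if self.border_softness < 0:
            raise ValidationError("border_softness must be >= 0")
        if self.beta_mean <= 0:
            raise ValidationError("beta_mean must be > 0")
        if self.alpha_mean <= 0 or self.alpha_sd < 0 or self.beta_sd < 0:
            raise ValidationError("growth parameter scales must be nonnegative")


def default_class_specs() -> tuple[PhantomClassSpec, PhantomClassSpec, PhantomClassSpec]:
    """The three default tumor classes.

    Growth-parameter scales follow the cohort estimates for the GL261
    mouse glioma (alpha 0.7 +/- 0.9, beta 0.15 +/- 0.04), U87 human glioma
    (1.2 +/- 0.8, 0.21 +/- 0.03) and Daoy medulloblastoma (0.9 +/- 0.5,
    0.08 +/- 0.04).  Texture correlation length and border softness are
    pairwise distinct: gliomas get sharp borders and fine texture, the
    medulloblastoma a diffuse border and coarse texture.
    """
    return (
        PhantomClassSpec("GL261", 1.5, 600.0, 80.0, 0.5, 0.7, 0.9, 0.15, 0.04),
        PhantomClassSpec("U87", 2.5, 500.0, 120.0, 1.0, 1.2, 0.8, 0.21, 0.03),
        PhantomClassSpec("Daoy", 4.0, 550.0, 150.0, 3.0, 0.9, 0.5, 0.08, 0.04),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort geometry and sampling plan.

    Defaults mirror the acquisition geometry of the emulated scans:
    256 x 256 in-plane matrix at 0.117 mm pixel spacing and 0.5 mm slice
    thickness, with weekly imaging sessions.
    """

    n_animals_per_class: int = 15
    imaging_days: tuple[float, ...] = (7.0, 14.0, 21.0, 28.0, 35.0, 42.0)
    volume_shape: tuple[int, int, int] = (40, 256, 256)
    pixel_spacing: float = 0.117
    slice_thickness: float = 0.5
    noise_sd: float = 5.0
    max_volume_mm3: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_class < 1:
            raise ValidationError("n_animals_per_class must be >= 1")
        days = tuple(self.imaging_days)
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError("imaging_days must be strictly increasing")
        if self.pixel_spacing <= 0 or self.slice_thickness <= 0:
            raise ValidationError("spacing must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.max_volume_mm3 <= 0:
            raise ValidationError("max_volume_mm3 must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.pixel_spacing**2 * self.slice_thickness


@dataclass
class GrowthSeries:
    """Longitudinal tumor volumes for one animal."""

    times: np.ndarray
    volumes: np.ndarray
    animal_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValidationError("times and volumes must be equal-length 1D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValidationError("volumes must be positive")


def _ellipsoid_radii_mm(volume_mm3: float, rng: np.random.Generator) -> np.ndarray:
    """Seeded anisotropic radii (z, y, x) in mm for a given volume."""
    ratios = rng.uniform(0.75, 1.35, size=3)
    base = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    return base * ratios


def generate_phantom_volume(
    spec: PhantomClassSpec,
    tumor_volume: float,
    shape: tuple[int, int, int],
    seed: int | np.random.SeedSequence,
    pixel_spacing: float = 0.117,
    slice_thickness: float = 0.5,
    noise_sd: float = 0.0,
    background_mean: float = _BACKGROUND_MEAN,
) -> tuple[ImageVolume, ROIMask]:
    """Render one tumor phantom and its binary mask.

    The tumor is a seeded ellipsoid voxelized to exactly
    ``round(tumor_volume / voxel_volume)`` voxels (the voxels with smallest
    ellipsoidal norm), so the mask volume matches the request to within
    half a voxel.  In-mask intensities come from a Gaussian random field
    with the spec's correlation length, mean and SD; the tumor blends into
    background over ``border_softness`` pixels; white measurement noise of
    SD ``noise_sd`` is added everywhere.
    """
    if tumor_volume <= 0:
        raise ValidationError("tumor_volume must be positive")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValidationError("shape must be a positive (slices, rows, cols) triple")
    voxvol = pixel_spacing**2 * slice_thickness
    n_target = int(round(tumor_volume / voxvol))
    if n_target < 1:
        raise ValidationError("tumor_volume is below one voxel")

    rng = np.random.default_rng(seed)
    radii = _ellipsoid_radii_mm(tumor_volume, rng)  # (z, y, x) mm
    spacing = np.array([slice_thickness, pixel_spacing, pixel_spacing])
    radii_vox = radii / spacing
    half = (np.asarray(shape) - 1) / 2.0
    if np.any(radii_vox > half):
        raise SizingError(
            f"tumor of {tumor_volume:.1f} mm^3 does not fit inside grid {shape}"
        )
    # seeded sub-voxel center jitter, clipped so the ellipsoid stays inside
    room = half - radii_vox
    jitter = rng.uniform(-1.0, 1.0, size=3) * np.minimum(room, 2.0)
    center = half + jitter

    zz = (np.arange(shape[0])[:, None, None] - center[0]) / radii_vox[0]
    yy = (np.arange(shape[1])[None, :, None] - center[1]) / radii_vox[1]
    xx = (np.arange(shape[2])[None, None, :] - center[2]) / radii_vox[2]
    q = zz**2 + yy**2 + xx**2
    flat = q.ravel()
    order = np.argpartition(flat, n_target - 1)[:n_target]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order] = True
    mask = mask.reshape(shape)

    # correlated in-plane random field, standardized then scaled to spec
    # moments; rendered only on the padded mask bounding box (the blend
    # weight w vanishes outside it) to keep large grids cheap
    pad = int(np.ceil(4.0 * max(spec.texture_correlation_length,
                                spec.border_softness))) + 2
    nz = np.nonzero(mask)
    lo3 = [max(0, int(nz[a].min()) - (pad if a else 1)) for a in range(3)]
    hi3 = [min(shape[a], int(nz[a].max()) + 1 + (pad if a else 1)) for a in range(3)]
    box = tuple(slice(l, h) for l, h in zip(lo3, hi3))
    box_shape = tuple(h - l for l, h in zip(lo3, hi3))

    white = rng.standard_normal(box_shape)
    fieldv = gaussian_filter(white, sigma=(0.0, spec.texture_correlation_length,
                                           spec.texture_correlation_length))
    # standardize on the in-mask voxels so the requested intensity moments
    # hold exactly inside the ROI (a finite correlated region otherwise
    # under-disperses relative to the field's marginal SD)
    in_mask = fieldv[mask[box]]
    fieldv = (fieldv - in_mask.mean()) / max(in_mask.std(), 1e-12)
    texture = spec.intensity_mean + spec.intensity_sd * fieldv

    if spec.border_softness > 0:
        w = gaussian_filter(mask[box].astype(float),
                            sigma=(0.0, spec.border_softness, spec.border_softness))
    else:
        w = mask[box].astype(float)
    voxels = np.full(shape, background_mean)
    voxels[box] += w * (texture - background_mean)
    if noise_sd > 0:
        voxels = voxels + noise_sd * rng.standard_normal(shape)

    volume = ImageVolume(
        voxels=voxels,
        pixel_spacing=(pixel_spacing, pixel_spacing),
        slice_thickness=slice_thickness,
        class_label=spec.class_label,
    )
    return volume, ROIMask(mask)


def generate_growth_series(
    alpha: float,
    beta: float,
    days: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    animal_id: Optional[str] = None,
) -> GrowthSeries:
    """Exponential volume series with multiplicative lognormal noise.

    Volumes are ``alpha * exp(beta * day)`` times a unit-mean lognormal
    factor whose coefficient of variation is ``noise_cv``; with
    ``noise_cv = 0`` the series is exactly the growth law.  Multiplicative
    noise keeps volumes positive at every noise level.
    """
    if alpha <= 0 or beta < 0:
        raise ValidationError("growth model requires alpha > 0 and beta >= 0")
    days = np.asarray(days, dtype=float)
    if days.size == 0 or np.any(np.diff(days) <= 0):
        raise ValidationError("days must be nonempty and strictly increasing")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    volumes = alpha * np.exp(beta * days)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factor = np.exp(sigma * rng.standard_normal(days.size) - sigma**2 / 2.0)
        volumes = volumes * factor
    return GrowthSeries(days, volumes, animal_id=animal_id)


def _sample_growth_params(
    spec: PhantomClassSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one animal's (alpha, beta).

    alpha is lognormal with the spec's mean and SD (moment matched); beta
    is normal.  Both are clipped to +/- 2.5 SD (and beta floored at 0.01
    per day) to keep every phantom inside the imaging field at the last
    session.
    """
    if spec.alpha_sd > 0:
        s2 = np.log1p((spec.alpha_sd / spec.alpha_mean) ** 2)
        mu = np.log(spec.alpha_mean) - s2 / 2.0
        alpha = float(np.exp(rng.normal(mu, np.sqrt(s2))))
        alpha = float(np.clip(alpha, spec.alpha_mean / 6.0,
                              spec.alpha_mean + 2.5 * spec.alpha_sd))
    else:
        alpha = spec.alpha_mean
    beta = float(rng.normal(spec.beta_mean, spec.beta_sd))
    beta = float(np.clip(beta, max(0.01, spec.beta_mean - 2.5 * spec.beta_sd),
                         spec.beta_mean + 2.5 * spec.beta_sd))
    return alpha, beta


@dataclass
class Cohort:
    """A lazily materialized phantom cohort.

    ``manifest`` is the scan-level table (scan_id, animal_id, class, day,
    volume_mm3); ``truth`` records each animal's sampled growth parameters.
    ``scan()`` regenerates a scan's voxel data deterministically from the
    stored per-scan seed.
    """

    config: CohortConfig
    specs: tuple[PhantomClassSpec, ...]
    manifest: pd.DataFrame
    truth: pd.DataFrame

    def scan(self, scan_id: str) -> tuple[ImageVolume, ROIMask]:
        row = self.manifest.set_index("scan_id").loc[scan_id]
        spec = next(s for s in self.specs if s.class_label == row["class"])
        volume, mask = generate_phantom_volume(
            spec,
            float(row["volume_mm3"]),
            self.config.volume_shape,
            np.random.SeedSequence(int(row["scan_seed"])),
            pixel_spacing=self.config.pixel_spacing,
            slice_thickness=self.config.slice_thickness,
            noise_sd=self.config.noise_sd,
        )
        volume.scan_id = scan_id
        volume.animal_id = str(row["animal_id"])
        volume.day_post_implant = float(row["day"])
        return volume, mask

    def iter_scans(self, scan_ids: Optional[Sequence[str]] = None):
        ids = self.manifest["scan_id"] if scan_ids is None else scan_ids
        for sid in ids:
            yield self.scan(sid)

    def growth_series(self, animal_id: str) -> GrowthSeries:
        sub = self.manifest[self.manifest["animal_id"] == animal_id].sort_values("day")
        if sub.empty:
            raise ValidationError(f"unknown animal {animal_id!r}")
        return GrowthSeries(
            sub["day"].to_numpy(), sub["volume_mm3"].to_numpy(), animal_id=animal_id
        )

    def first_session_ids(self) -> list[str]:
        first = self.manifest.sort_values("day").groupby("animal_id", sort=False).head(1)
        return list(first.sort_index()["scan_id"])

    def save(self, directory, dialect: str = "nifti") -> Path:
        """Materialize volumes, masks and the manifest CSV to disk."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths_vol, paths_mask = [], []
        for sid in self.manifest["scan_id"]:
            volume, mask = self.scan(sid)
            if dialect == "nifti":
                pv = directory / f"{sid}_image.nii.gz"
                save_nifti(volume, pv)
            elif dialect == "dicom":
                pv = directory / f"{sid}_image"
                save_dicom_series(volume, pv)
            else:
                raise ValidationError(f"unknown dialect {dialect!r}")
            pm = directory / f"{sid}_mask.nii.gz"
            mask_vol = ImageVolume(
                mask.voxels.astype(np.uint8),
                pixel_spacing=volume.pixel_spacing,
                slice_thickness=volume.slice_thickness,
            )
            save_nifti(mask_vol, pm)
            paths_vol.append(str(pv))
            paths_mask.append(str(pm))
        man = self.manifest.copy()
        man["image_path"] = paths_vol
        man["mask_path"] = paths_mask
        man.to_csv(directory / "manifest.csv", index=False)
        return directory / "manifest.csv"


def generate_cohort(
    config: CohortConfig,
    specs: Optional[Sequence[PhantomClassSpec]] = None,
    growth_sd_scale: float = 1.0,
) -> Cohort:
    """Sample a cohort plan: per-animal growth parameters and scan schedule.

    ``growth_sd_scale`` multiplies every class's alpha_sd and beta_sd — the
    dial used to study how growth-parameter spread affects downstream
    prediction.  Scan voxel data is not generated here; each scan row
    carries a derived seed from which :meth:`Cohort.scan` rebuilds it
    bit-identically.
    """
    if specs is None:
        specs = default_class_specs()
    specs = tuple(specs)
    if len(specs) < 1:
        raise ValidationError("at least one class spec required")
    if growth_sd_scale != 1.0:
        specs = tuple(
            replace(s, alpha_sd=s.alpha_sd * growth_sd_scale,
                    beta_sd=s.beta_sd * growth_sd_scale)
            for s in specs
        )
    base = np.random.SeedSequence(config.seed)
    child_params, child_scans = base.spawn(2)
    param_rng = np.random.default_rng(child_params)
    scan_seed_rng = np.random.default_rng(child_scans)

    rows, truth_rows = [], []
    for spec in specs:
        for a in range(config.n_animals_per_class):
            animal_id = f"{spec.class_label}_{a:03d}"
            alpha, beta = _sample_growth_params(spec, param_rng)
            truth_rows.append(
                {"animal_id": animal_id, "class": spec.class_label,
                 "alpha": alpha, "beta": beta}
            )
            for d_idx, day in enumerate(config.imaging_days):
                v = alpha * np.exp(beta * day)
                # tumor-burden cutoff: fast growers leave the schedule early
                # (classes get different scan counts, as in longitudinal
                # studies); the first two sessions are always kept so every
                # animal supports a growth fit
                if d_idx >= 2 and v > config.max_volume_mm3:
                    break
                n_vox = int(round(v / config.voxel_volume_mm3))
                rows.append(
                    {
                        "scan_id": f"{animal_id}_d{int(day):03d}",
                        "animal_id": animal_id,
                        "class": spec.class_label,
                        "day": float(day),
                        "volume_mm3": n_vox * config.voxel_volume_mm3,
                        "scan_seed": int(scan_seed_rng.integers(0, 2**31 - 1)),
                    }
                )
    manifest = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    # validate sizing up front so failures surface at planning time
    voxvol = config.voxel_volume_mm3
    spacing = np.array([config.slice_thickness, config.pixel_spacing, config.pixel_spacing])
    half = (np.asarray(config.volume_shape) - 1) / 2.0
    vmax = manifest["volume_mm3"].max()
    # worst-case long ellipsoid axis over the seeded ratio range [0.75, 1.35]
    rmax = 1.35 * (3.0 * vmax / (4.0 * np.pi * 0.75 * 0.75 * 1.35)) ** (1 / 3.0)
    if np.any(rmax / spacing > half):
        raise SizingError(
            f"largest scheduled tumor ({vmax:.0f} mm^3) cannot fit the grid "
            f"{config.volume_shape}; shorten imaging_days or enlarge the grid"
        )
    return Cohort(config=config, specs=specs, manifest=manifest, truth=truth)
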