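"""Synthetic DIXON-like phantom cohort generator.

Builds paired water-only / fat-only 12-bit slice matrices containing a
prostate ellipse, a periprostatic fat annulus of mostly white adipose
tissue (high fat fraction), and sparse brown-fat blobs (lower fat
fraction, hence higher water-to-oil ratio), plus group-conditional iPSA
draws, so the downstream pipeline can be exercised end to end without
patient data.

All randomness flows from explicit integer seeds; per-patient sub-seeds
are derived from the master seed with ``numpy.random.SeedSequence`` spawn
keys, so cohorts are reproducible independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    MAX_RAW_LEVEL,
    RawImageMatrix,
    RoiMask,
    make_roi_mask,
)

RiskGroup = str  # "low" | "intermediate" | "high"
_VALID_GROUPS = ("low", "intermediate", "high")


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, tissue composition and noise of one synthetic slice.

    ``wat_fat_fraction`` / ``bat_fat_fraction`` are the fat signal
    fractions fat/(water+fat) of white and brown adipose voxels; brown
    fat must have the lower fat fraction (higher water-to-oil ratio).
    """

    image_height: int = 128
    image_width: int = 128
    prostate_center: tuple[int, int] = (64, 64)
    prostate_radii: tuple[int, int] = (24, 28)
    annulus_width: int = 14
    wat_fat_fraction: float = 0.9
    bat_fat_fraction: float = 0.55
    bat_blob_count: int = 3
    bat_blob_radius: int = 3
    signal_peak: int = 4000
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bat_fat_fraction < self.wat_fat_fraction < 1.0):
            raise ValueError(
                "fat fractions must satisfy 0 < bat_fat_fraction < "
                f"wat_fat_fraction < 1; got bat={self.bat_fat_fraction}, "
                f"wat={self.wat_fat_fraction}"
            )
        if self.signal_peak > MAX_RAW_LEVEL or self.signal_peak <= 0:
            raise ValueError(
                f"signal_peak must be in (0, {MAX_RAW_LEVEL}], got {self.signal_peak}"
            )
        if self.bat_blob_count < 0 or self.bat_blob_radius < 0:
            raise ValueError("blob count and radius must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        r0, c0 = self.prostate_center
        ra, rb = self.prostate_radii
        outer_a, outer_b = ra + self.annulus_width, rb + self.annulus_width
        if (
            r0 - outer_a < 0
            or r0 + outer_a >= self.image_height
            or c0 - outer_b < 0
            or c0 + outer_b >= self.image_width
        ):
            raise ValueError(
                f"prostate ellipse {self.prostate_radii} plus annulus width "
                f"{self.annulus_width} centred at {self.prostate_center} does "
                f"not fit a {self.image_height}x{self.image_width} image"
            )


@dataclass(frozen=True)
class GroupProfile:
    """Per-risk-group cohort composition and iPSA moments."""

    group_label: RiskGroup
    n_patients: int
    ipsa_mean: float
    ipsa_sd: float
    bat_blob_count_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.group_label not in _VALID_GROUPS:
            raise ValueError(f"unknown risk group {self.group_label!r}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.ipsa_mean <= 0:
            raise ValueError("ipsa_mean must be positive")
        if self.ipsa_sd < 0:
            raise ValueError("ipsa_sd must be nonnegative")
        lo, hi = self.bat_blob_count_range
        if lo < 0 or hi < lo:
            raise ValueError("bat_blob_count_range must be a valid interval")


#: Cohort composition matching the studied 21-patient population: group
#: sizes 4/4/13 with iPSA mean (SD) of 6.7 (2.3) / 10.4 (3.6) / 51.9 (50.6)
#: ng/ml.  Blob-count ranges are free parameters chosen so brown-fat burden
#: rises with risk group.
DEFAULT_PROFILES: tuple[GroupProfile, ...] = (
    GroupProfile("low", 4, 6.7, 2.3, (0, 1)),
    GroupProfile("intermediate", 4, 10.4, 3.6, (2, 4)),
    GroupProfile("high", 13, 51.9, 50.6, (3, 6)),
)


@dataclass
class PatientRecord:
    """One synthetic (or loaded) patient: clinical covariates plus slices."""

    patient_id: str
    risk_group: RiskGroup
    ipsa: float
    slices: list[tuple[RawImageMatrix, RawImageMatrix, RoiMask]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk_group not in _VALID_GROUPS:
            raise ValueError(f"unknown risk group {self.risk_group!r}")
        if self.ipsa <= 0:
            raise ValueError("ipsa must be positive")
        if not self.slices:
            raise ValueError("patient record needs at least one slice")


# ---------------------------------------------------------------------------
# Slice generation
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[int, int],
    radii: tuple[float, float],
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    r0, c0 = center
    ra, rb = radii
    return ((rr - r0) / ra) ** 2 + ((cc - c0) / rb) ** 2 <= 1.0


def generate_phantom_slice(
    params: PhantomParams, *, with_truth: bool = False
):
    """Generate one paired (water, fat, annulus mask) phantom slice.

    Composition per compartment (before noise), with peak total signal S:

    * annulus WAT voxels: fat = wat_fat_fraction * S, water = rest;
    * annulus BAT blob voxels: fat = bat_fat_fraction * S, water = rest;
    * prostate interior: water-dominant tissue signal at 0.5 S;
    * background: zero signal.

    Gaussian noise of ``noise_sd`` is added per channel, then values are
    rounded and clipped to the 12-bit range.  Fully deterministic for a
    fixed ``params.seed``.

    With ``with_truth=True`` additionally returns the boolean ground-truth
    blob mask (blob voxels inside the annulus).
    """
    p = params
    shape = (p.image_height, p.image_width)
    rng = np.random.default_rng(p.seed)

    prostate = _ellipse_mask(shape, p.prostate_center, p.prostate_radii)
    outer = _ellipse_mask(
        shape,
        p.prostate_center,
        (p.prostate_radii[0] + p.annulus_width, p.prostate_radii[1] + p.annulus_width),
    )
    annulus = outer & ~prostate

    water = np.zeros(shape, dtype=float)
    fat = np.zeros(shape, dtype=float)

    s = float(p.signal_peak)
    water[annulus] = (1.0 - p.wat_fat_fraction) * s
    fat[annulus] = p.wat_fat_fraction * s

    blob_mask = np.zeros(shape, dtype=bool)
    if p.bat_blob_count > 0:
        coords = np.argwhere(annulus)
        centers = coords[rng.integers(0, len(coords), size=p.bat_blob_count)]
        for r0, c0 in centers:
            blob = _ellipse_mask(
                shape, (int(r0), int(c0)), (max(p.bat_blob_radius, 1e-9),) * 2
            )
            blob_mask |= blob & annulus
        water[blob_mask] = (1.0 - p.bat_fat_fraction) * s
        fat[blob_mask] = p.bat_fat_fraction * s

    # water-dominant prostate interior so renderings show the anatomy
    water[prostate] = 0.45 * s
    fat[prostate] = 0.05 * s

    if p.noise_sd > 0:
        water = water + rng.normal(0.0, p.noise_sd, shape)
        fat = fat + rng.normal(0.0, p.noise_sd, shape)

    water_i = np.clip(np.rint(water), 0, MAX_RAW_LEVEL).astype(np.int32)
    fat_i = np.clip(np.rint(fat), 0, MAX_RAW_LEVEL).astype(np.int32)

    mask = make_roi_mask(annulus)
    result = (
        RawImageMatrix(water_i, "water"),
        RawImageMatrix(fat_i, "fat"),
        mask,
    )
    if with_truth:
        return (*result, blob_mask)
    return result


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------


def lognormal_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_ipsa(profile: GroupProfile, seed: int, size: int | None = None):
    """Draw iPSA value(s) for a risk group.

    The draw is log-normal, moment-matched to the profile's arithmetic
    mean/SD (iPSA is positive and right-skewed; in the high-risk group the
    SD is about as large as the mean).  ``ipsa_sd == 0`` degenerates to
    the point mass at the mean.
    """
    rng = np.random.default_rng(seed)
    n = 1 if size is None else size
    if profile.ipsa_sd == 0:
        draws = np.full(n, profile.ipsa_mean)
    else:
        mu, sigma = lognormal_moment_params(profile.ipsa_mean, profile.ipsa_sd)
        draws = rng.lognormal(mu, sigma, size=n)
    return float(draws[0]) if size is None else draws


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _child_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed from the master seed and an index path."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def generate_cohort(
    profiles: Sequence[GroupProfile] = DEFAULT_PROFILES,
    params: PhantomParams = PhantomParams(),
    slices_per_patient: int = 1,
    seed: int = 0,
) -> list[PatientRecord]:
    """Generate a full synthetic cohort, one record per patient.

    Each patient gets an iPSA draw from their group profile, a blob count
    drawn uniformly from the group's range, and ``slices_per_patient``
    phantom slices.  Sub-seeds are derived from ``seed`` per patient and
    per slice, so any subset of the cohort is reproducible.
    """
    if not profiles:
        raise ValueError("at least one group profile is required")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")

    records: list[PatientRecord] = []
    patient_idx = 0
    for profile in profiles:
        for _ in range(profile.n_patients):
            pid = f"P{patient_idx + 1:03d}"
            ipsa = sample_ipsa(profile, _child_seed(seed, patient_idx, 0))
            blob_rng = np.random.default_rng(_child_seed(seed, patient_idx, 1))
            lo, hi = profile.bat_blob_count_range
            blob_count = int(blob_rng.integers(lo, hi + 1))
            slices = []
            for s in range(slices_per_patient):
                sp = replace(
                    params,
                    bat_blob_count=blob_count,
                    seed=_child_seed(seed, patient_idx, 2 + s),
                )
                slices.append(generate_phantom_slice(sp))
            records.append(
                PatientRecord(
                    patient_id=pid,
                    risk_group=profile.group_label,
                    ipsa=ipsa,
                    slices=slices,
                    meta={"bat_blob_count": blob_count},
                )
            )
            patient_idx += 1
    return records
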