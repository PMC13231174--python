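"""Synthetic glioma phantoms and synthetic survival cohorts.

The 3D phantom emulates the signal contract of the segmentation problem: a
brain sphere containing nested lesion compartments (necrosis inside
contrast-enhancing tumor inside edema), where a configurable fraction of the
edema is ground-truth nCET. The nCET class has a lower FLAIR mean than
vasogenic edema while the two classes share essentially the same T2 mean, so
FLAIR is the separating channel — the qualitative pattern observed in real
glioblastoma. A few small satellite nCET islands are placed near the outer
edema boundary so that the boundary-cleanup stage is exercised.

The cohort simulator draws a TFHI per patient from a Beta distribution and
event times from an exponential whose hazard jumps by a known ratio when
TFHI exceeds a known threshold, with independent uniform censoring. It is the
ground-truth generator used to test threshold search and Cox recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import (
    BACKGROUND,
    CET,
    EDEMA,
    NECROSIS,
    AnatomyLabelMap,
    IntensityVolume,
)

#: default class means in arbitrary scanner units; noise_sd = 1 puts the
#: FLAIR nCET/vasogenic separation at 3 noise SDs
DEFAULT_MEANS = {
    "brain": {"t2": 10.0, "flair": 10.0},
    "necrosis": {"t2": 5.0, "flair": 4.0},
    "cet": {"t2": 12.0, "flair": 12.0},
    "vasogenic": {"t2": 15.0, "flair": 16.0},
    "ncet": {"t2": 15.0, "flair": 13.0},
}


@dataclass
class PhantomConfig:
    """Geometry, intensity and noise settings of the synthetic case."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    necrosis_radius_mm: float = 5.0
    cet_radius_mm: float = 9.0
    edema_radius_mm: float = 16.0
    brain_radius_mm: float = 26.0
    ncet_fraction: float = 0.25
    n_satellite_islands: int = 3
    island_size_range: tuple[int, int] = (20, 60)
    class_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MEANS.items()})
    noise_sd: float = 1.0
    bias_field_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ncet_fraction <= 1.0):
            raise ValueError("ncet_fraction must lie in [0, 1]")
        radii = (self.necrosis_radius_mm, self.cet_radius_mm, self.edema_radius_mm)
        if not (radii[0] < radii[1] < radii[2] < self.brain_radius_mm):
            raise ValueError("radii must be strictly increasing: necrosis < CET < edema < brain")
        half_extent = min(
            sh * sp / 2.0 for sh, sp in zip(self.grid_shape, self.spacing)
        )
        if self.brain_radius_mm >= half_extent:
            raise ValueError("brain radius exceeds the grid")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be >= 0")

    @property
    def flair_separation(self) -> float:
        """Configured vasogenic-minus-nCET FLAIR mean difference."""
        return self.class_means["vasogenic"]["flair"] - self.class_means["ncet"]["flair"]


@dataclass
class PhantomCase:
    """One synthetic case with ground-truth nCET mask."""

    t2: IntensityVolume
    flair: IntensityVolume
    anatomy: AnatomyLabelMap
    truth_ncet_mask: np.ndarray
    config: PhantomConfig


def _radius_mm(shape, spacing) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return np.sqrt(d2)


def generate_phantom(config: PhantomConfig | None = None) -> PhantomCase:
    """Build one seeded phantom case.

    The achieved nCET voxel fraction matches ``ncet_fraction`` to within
    rounding (a handful of voxels) before noise is added, and the call is
    bit-reproducible for a fixed seed.
    """
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing, dtype=np.float64)
    r = _radius_mm(shape, spacing)

    brain = r <= config.brain_radius_mm
    necrosis = r <= config.necrosis_radius_mm
    cet = (r > config.necrosis_radius_mm) & (r <= config.cet_radius_mm)
    edema = (r > config.cet_radius_mm) & (r <= config.edema_radius_mm)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[necrosis] = NECROSIS
    labels[cet] = CET
    labels[edema] = EDEMA

    n_edema = int(edema.sum())
    target = int(round(config.ncet_fraction * n_edema))
    truth = np.zeros(shape, dtype=bool)

    # satellite islands near the outer edema boundary (within ~4 mm of it)
    if target > 0 and config.n_satellite_islands > 0:
        lo, hi = config.island_size_range
        edema_r = r.copy()
        for _ in range(config.n_satellite_islands):
            size = int(rng.integers(lo, hi + 1))
            placed = False
            for _attempt in range(50):
                # island center in the outer shell of the edema
                shell = (
                    edema
                    & (r >= config.edema_radius_mm - 3.0)
                    & (r <= config.edema_radius_mm - 1.0)
                    & ~truth
                )
                cand = np.flatnonzero(shell.ravel())
                if cand.size == 0:
                    break
                c_flat = int(cand[rng.integers(cand.size)])
                c_idx = np.unravel_index(c_flat, shape)
                c_mm = (np.asarray(c_idx) - (np.asarray(shape) - 1) / 2.0) * spacing
                rad = (3.0 * size * np.prod(spacing) / (4.0 * np.pi)) ** (1.0 / 3.0)
                grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
                d2 = sum(
                    ((g - (sh - 1) / 2.0) * sp - cm) ** 2
                    for g, sh, sp, cm in zip(grids, shape, spacing, c_mm)
                )
                ball = (d2 <= rad**2) & edema
                if ball.sum() == 0 or (ball & truth).any():
                    continue
                truth |= ball
                placed = True
                break
            if not placed and truth.sum() == 0 and config.ncet_fraction > 0:
                raise RuntimeError("could not place satellite nCET islands")
        # never let islands overshoot the target
        if truth.sum() > target:
            truth[:] = False

    # main nCET region: innermost edema voxels (adjacent to the CET rim),
    # filled up to the exact target count
    remaining = target - int(truth.sum())
    if remaining > 0:
        cand_flat = np.flatnonzero((edema & ~truth).ravel())
        order = np.argsort(r.ravel()[cand_flat], kind="stable")
        truth.ravel()[cand_flat[order[:remaining]]] = True

    means = config.class_means
    t2 = np.zeros(shape)
    flair = np.zeros(shape)
    regions = [
        (brain & (labels == BACKGROUND), "brain"),
        (necrosis, "necrosis"),
        (cet, "cet"),
        (edema & ~truth, "vasogenic"),
        (truth, "ncet"),
    ]
    for mask, key in regions:
        t2[mask] = means[key]["t2"]
        flair[mask] = means[key]["flair"]

    if config.bias_field_amplitude > 0:
        # smooth multiplicative low-order polynomial field, mean 1
        coords = [np.linspace(-1, 1, s) for s in shape]
        gx, gy, gz = np.meshgrid(*coords, indexing="ij")
        poly = gx + 0.5 * gy - 0.3 * gz + 0.4 * gx * gy
        poly = poly / np.abs(poly).max()
        gain = 1.0 + config.bias_field_amplitude * poly
        t2 *= gain
        flair *= gain

    if config.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, config.noise_sd, shape) * brain
        flair = flair + rng.normal(0.0, config.noise_sd, shape) * brain

    affine = np.diag([*spacing, 1.0])
    return PhantomCase(
        t2=IntensityVolume(t2, spacing, affine, name="t2"),
        flair=IntensityVolume(flair, spacing, affine, name="flair"),
        anatomy=AnatomyLabelMap(labels, spacing, affine, name="anatomy"),
        truth_ncet_mask=truth,
        config=config,
    )


@dataclass
class SurvivalSimConfig:
    """Ground-truth survival model: hazard jumps by ``hazard_ratio`` when the
    patient's TFHI exceeds ``threshold``."""

    n_patients: int = 200
    tfhi_beta: tuple[float, float] = (2.0, 2.0)
    threshold: float = 0.70
    hazard_ratio: float = 2.0
    baseline_hazard: float = np.log(2.0) / 400.0  # median OS ~400 days below threshold
    censoring_window: tuple[float, float] = (200.0, 1500.0)
    include_covariates: bool = False
    mgmt_hazard_ratio: float = 1.9
    mgmt_missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard_ratio and baseline_hazard must be > 0")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


def generate_survival_cohort(config: SurvivalSimConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort table (os_days, event, tfhi, optional covariates)."""
    config = config or SurvivalSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    a, b = config.tfhi_beta
    tfhi = rng.beta(a, b, n)
    high = tfhi > config.threshold
    hazard = config.baseline_hazard * np.where(high, config.hazard_ratio, 1.0)

    df = pd.DataFrame({"tfhi": tfhi})
    if config.include_covariates:
        df["age"] = rng.uniform(30.0, 85.0, n)
        df["gender"] = rng.integers(0, 2, n).astype(float)
        mgmt = rng.integers(0, 2, n).astype(float)
        missing = rng.uniform(size=n) < config.mgmt_missing_rate
        df["mgmt"] = np.where(missing, np.nan, mgmt)
        df["edema_volume"] = rng.lognormal(mean=10.5, sigma=0.5, size=n)
        df["rcbv_p90_ncet"] = rng.lognormal(mean=0.7, sigma=0.3, size=n)
        df["cet_edema_ratio"] = np.clip(
            0.5 * tfhi + rng.normal(0.15, 0.08, n), 0.0, 1.0
        )
        hazard = hazard * config.mgmt_hazard_ratio ** np.nan_to_num(mgmt * ~missing)

    event_time = rng.exponential(1.0 / hazard)
    lo, hi = config.censoring_window
    censor_time = rng.uniform(lo, hi, n)
    df["os_days"] = np.minimum(event_time, censor_time)
    df["event"] = (event_time <= censor_time).astype(int)
    df["true_high_risk"] = high.astype(int)
    return df
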