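"""Per-case statistical and practical validation of the edema split.

Two criteria, applied to the FLAIR channel (the separating sequence):

- a Mann-Whitney U test between nCET and vasogenic intensities must reach
  P < .01 (statistical significance);
- the relative region-mean intensity difference

  .. math::

     \\%\\Delta I = \\frac{|\\bar I_{nCET} - \\bar I_{vasog}|}
                        {\\max(I_{brain}) - \\min(I_{brain})} \\cdot 100

  normalized by the whole-brain intensity range, must exceed 5%
  (practical significance).

T2 results are computed and reported alongside for completeness; both
thresholds are configurable. Degenerate inputs (an empty subregion) yield a
non-significant report rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .imaging_io import IntensityVolume
from .postprocess import EdemaSplit


@dataclass
class ValidationReport:
    u_stat: dict = field(default_factory=dict)            # per sequence
    p_value: dict = field(default_factory=dict)           # two-sided, per sequence
    percent_delta_i: dict = field(default_factory=dict)   # per sequence
    region_means: dict = field(default_factory=dict)
    brain_range: dict = field(default_factory=dict)
    statistically_significant: bool = False
    practically_significant: bool = False
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "u_stat": self.u_stat,
            "p_value": self.p_value,
            "percent_delta_i": self.percent_delta_i,
            "region_means": self.region_means,
            "brain_range": self.brain_range,
            "statistically_significant": self.statistically_significant,
            "practically_significant": self.practically_significant,
            "reason": self.reason,
        }


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Uses exact enumeration for small tie-free samples (both n <= 20) and the
    normal approximation with tie-corrected variance otherwise.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    small = a.size <= 20 and b.size <= 20
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_delta_intensity(ncet_values, vasog_values, brain_values, summary: str = "mean") -> float:
    """%ΔI: absolute region-summary difference over the brain intensity range, x100."""
    ncet = np.asarray(ncet_values, dtype=np.float64)
    vasog = np.asarray(vasog_values, dtype=np.float64)
    brain = np.asarray(brain_values, dtype=np.float64)
    if ncet.size == 0 or vasog.size == 0 or brain.size == 0:
        raise ValueError("all three samples must be non-empty")
    rng = float(brain.max() - brain.min())
    if rng <= 0:
        raise ValueError("degenerate image: zero brain intensity range")
    agg = np.median if summary == "median" else np.mean
    return float(abs(agg(ncet) - agg(vasog)) / rng * 100.0)


def validate_case(
    split: EdemaSplit,
    t2: IntensityVolume,
    flair: IntensityVolume,
    brain_mask: np.ndarray | None = None,
    alpha: float = 0.01,
    delta_i_cutoff: float = 5.0,
    summary: str = "mean",
) -> ValidationReport:
    """Run both validation criteria on a case.

    ``brain_mask`` defaults to all strictly positive FLAIR voxels (the inputs
    are assumed skull-stripped, so nonzero means in-brain). The significance
    flags are driven by the FLAIR channel; thresholds are strict inequalities
    (p < alpha, %ΔI > cutoff).
    """
    report = ValidationReport()
    if brain_mask is None:
        brain_mask = flair.data > 0
    brain_mask = np.asarray(brain_mask, dtype=bool)

    if not split.ncet_mask.any() or not split.vasogenic_mask.any():
        report.reason = "empty region"
        return report

    for label, vol in (("flair", flair), ("t2", t2)):
        ncet_vals = vol.data[split.ncet_mask]
        vasog_vals = vol.data[split.vasogenic_mask]
        brain_vals = vol.data[brain_mask]
        u, p = mann_whitney(ncet_vals, vasog_vals)
        report.u_stat[label] = u
        report.p_value[label] = p
        report.percent_delta_i[label] = percent_delta_intensity(
            ncet_vals, vasog_vals, brain_vals, summary=summary
        )
        report.region_means[label] = {
            "ncet": float(ncet_vals.mean()),
            "vasogenic": float(vasog_vals.mean()),
        }
        report.brain_range[label] = {
            "min": float(brain_vals.min()),
            "max": float(brain_vals.max()),
        }

    report.statistically_significant = bool(report.p_value["flair"] < alpha)
    report.practically_significant = bool(report.percent_delta_i["flair"] > delta_i_cutoff)
    return report
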