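"""Prognostic evaluation of TFHI: c-index threshold optimization,
Kaplan-Meier stratification and Cox regression.

The dichotomization strategy follows the biomarker-evaluation design the
index was introduced with: candidate cutoffs are the midpoints between
consecutive sorted unique TFHI values; for each cutoff the binary indicator
1[TFHI > t] serves as the risk score, and the cutoff maximizing Harrell's
concordance index is retained (ties broken toward the smallest cutoff). The
stratified groups are then compared with Kaplan-Meier curves (median OS =
earliest time the survival curve reaches 0.5) and a univariate Cox model
(hazard ratio, 95% CI, Wald p).

Multivariable Cox models use the cohort's covariate encoding: gender male=0 /
female=1, MGMT methylated=0 / unmethylated=1 with missing values imputed by
prevalence, and continuous covariates min-max scaled to [0, 1]. Models are
built incrementally (clinical -> +perfusion -> +volumetric), each with and
without TFHI. Cox fitting and Kaplan-Meier estimation are delegated to
lifelines (Efron tie handling); the c-index and threshold search are computed
here by explicit pair enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

REQUIRED_COLUMNS = ("os_days", "event", "tfhi")

#: incremental model tiers (column sets); perfusion enters before volumetry
TIERS: dict[str, list[str]] = {
    "clinical": ["age", "gender", "mgmt"],
    "clinical+perfusion": ["age", "gender", "mgmt", "rcbv_p90_ncet"],
    "clinical+perfusion+volumetric": [
        "age",
        "gender",
        "mgmt",
        "rcbv_p90_ncet",
        "edema_volume",
    ],
}
TIERS["full"] = TIERS["clinical+perfusion+volumetric"]

CONTINUOUS_COLUMNS = ("age", "edema_volume", "rcbv_p90_ncet", "tfhi", "cet_edema_ratio")


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-patient survival table invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if (table["os_days"] <= 0).any():
        raise ValueError("os_days must be strictly positive")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    if ((table["tfhi"] < 0) | (table["tfhi"] > 1)).any():
        raise ValueError("tfhi must lie in [0, 1]")
    return table


def harrell_cindex(risk_scores, os_days, event) -> float:
    """Harrell's concordance index by explicit pair enumeration.

    Usable pairs are those whose shorter survival time ends in an event
    (tied times are usable only when exactly one member has the event);
    concordant pairs have the higher risk on the shorter survivor, risk ties
    count 0.5.
    """
    risk = np.asarray(risk_scores, dtype=np.float64)
    t = np.asarray(os_days, dtype=np.float64)
    e = np.asarray(event, dtype=bool)
    if risk.size < 2:
        raise ValueError("need at least 2 patients")
    if not e.any():
        raise ValueError("need at least 1 event")
    # ordered pairs (i, j): i is the shorter, event-bearing member
    shorter = t[:, None] < t[None, :]
    tied_time = t[:, None] == t[None, :]
    usable = (shorter & e[:, None]) | (tied_time & e[:, None] & ~e[None, :])
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (all times tied or censored)")
    higher = risk[:, None] > risk[None, :]
    tied_risk = risk[:, None] == risk[None, :]
    concordant = int((usable & higher).sum())
    ties = int((usable & tied_risk).sum())
    return (concordant + 0.5 * ties) / n_usable


def optimal_threshold(tfhi_values, os_days, event) -> tuple[float, float]:
    """Exhaustive c-index maximization over midpoint candidate cutoffs.

    Returns ``(threshold, c_index)``; c-index ties break toward the smallest
    threshold.
    """
    tfhi = np.asarray(tfhi_values, dtype=np.float64)
    uniq = np.unique(tfhi)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct TFHI values")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_c = candidates[0], -np.inf
    for t in candidates:
        c = harrell_cindex((tfhi > t).astype(float), os_days, event)
        if c > best_c:
            best_t, best_c = t, c
    return float(best_t), float(best_c)


@dataclass
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def median(self) -> float | None:
        """Earliest time with S(t) <= 0.5, or None if never reached."""
        idx = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[idx[0]]) if idx.size else None


def kaplan_meier(os_days, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator (via lifelines)."""
    t = np.asarray(os_days, dtype=np.float64)
    if t.size == 0:
        raise ValueError("need at least 1 patient")
    kmf = KaplanMeierFitter()
    kmf.fit(t, np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=np.float64),
        survival=sf.iloc[:, 0].to_numpy(dtype=np.float64),
    )


def median_os(curve: KMCurve) -> float | None:
    return curve.median()


@dataclass
class CoxModelResult:
    """One fitted Cox proportional-hazards model."""

    variables: list[str]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    wald_p: dict[str, float]
    c_index: float
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "coefficients": self.coefficients,
            "hazard_ratios": self.hazard_ratios,
            "ci95": {
                v: [self.ci_lower[v], self.ci_upper[v]] for v in self.variables
            },
            "wald_p": self.wald_p,
            "c_index": self.c_index,
            "n": self.n,
            "n_events": self.n_events,
            "warnings": self.warnings,
        }


def cox_fit(design: pd.DataFrame, os_days, event) -> CoxModelResult:
    """Cox proportional-hazards fit (Efron ties) with Wald inference.

    ``design`` holds only covariate columns. Raises on non-convergence with
    lifelines' diagnostics attached; a monotone-likelihood/complete-separation
    situation surfaces as a warning in the result.
    """
    df = design.copy()
    covariates = list(df.columns)
    if not covariates:
        raise ValueError("empty design matrix")
    df["os_days"] = np.asarray(os_days, dtype=np.float64)
    df["event"] = np.asarray(event, dtype=int)
    if df["event"].sum() < 1:
        raise ValueError("need at least 1 event")
    notes: list[str] = []
    cph = CoxPHFitter()
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="os_days", event_col="event")
        except ConvergenceError as err:
            raise RuntimeError(f"Cox model failed to converge: {err}") from err
    for w in caught:
        msg = str(w.message)
        if "convergence" in msg.lower() or "separation" in msg.lower():
            notes.append(msg)

    summary = cph.summary
    return CoxModelResult(
        variables=covariates,
        coefficients={v: float(summary.loc[v, "coef"]) for v in covariates},
        hazard_ratios={v: float(summary.loc[v, "exp(coef)"]) for v in covariates},
        ci_lower={v: float(np.exp(summary.loc[v, "coef lower 95%"])) for v in covariates},
        ci_upper={v: float(np.exp(summary.loc[v, "coef upper 95%"])) for v in covariates},
        wald_p={v: float(summary.loc[v, "p"]) for v in covariates},
        c_index=float(cph.concordance_index_),
        n=len(df),
        n_events=int(df["event"].sum()),
        warnings=notes,
    )


def encode_covariates(
    table: pd.DataFrame,
    tier: str = "full",
    include_tfhi: bool = True,
    impute: str = "modal",
    seed: int | None = None,
) -> pd.DataFrame:
    """Build the Cox design matrix with the cohort encoding.

    MGMT missing values are imputed to the more prevalent observed category
    (``impute="modal"``, deterministic; ties go to methylated = 0) or drawn
    proportionally to the observed prevalence (``impute="proportional"``,
    seeded). Continuous covariates are min-max scaled to [0, 1] using the
    cohort min/max; a zero-range column is an error.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; choose from {sorted(TIERS)}")
    columns = list(TIERS[tier])
    if include_tfhi:
        columns.append("tfhi")
    missing_cols = [c for c in columns if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks columns {missing_cols} for tier {tier!r}")
    design = table[columns].copy().astype(float)

    if "mgmt" in design.columns:
        mgmt = design["mgmt"]
        observed = mgmt.dropna()
        if observed.empty:
            raise ValueError("all MGMT values missing; cannot impute by prevalence")
        if mgmt.isna().any():
            if impute == "modal":
                n1 = float((observed == 1).sum())
                n0 = float((observed == 0).sum())
                fill = 1.0 if n1 > n0 else 0.0  # tie -> methylated (0)
                design["mgmt"] = mgmt.fillna(fill)
            elif impute == "proportional":
                rng = np.random.default_rng(seed)
                p1 = float((observed == 1).mean())
                draws = (rng.uniform(size=int(mgmt.isna().sum())) < p1).astype(float)
                vals = mgmt.to_numpy(copy=True)
                vals[np.isnan(vals)] = draws
                design["mgmt"] = vals
            else:
                raise ValueError(f"unknown imputation mode {impute!r}")

    for col in design.columns:
        if col in CONTINUOUS_COLUMNS:
            lo, hi = float(design[col].min()), float(design[col].max())
            if hi - lo <= 0:
                raise ValueError(f"zero-range continuous column {col!r}")
            design[col] = (design[col] - lo) / (hi - lo)
    return design


@dataclass
class StratificationResult:
    threshold: float
    c_index: float
    hazard_ratio: float
    ci95: tuple[float, float]
    wald_p: float
    km_high: KMCurve
    km_low: KMCurve
    median_high: float | None
    median_low: float | None
    delta_os_days: float | None
    n_high: int
    n_low: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "c_index": self.c_index,
            "hazard_ratio": self.hazard_ratio,
            "ci95": list(self.ci95),
            "wald_p": self.wald_p,
            "median_os_high": self.median_high,
            "median_os_low": self.median_low,
            "delta_os_days": self.delta_os_days,
            "n_high": self.n_high,
            "n_low": self.n_low,
        }


def stratify(
    table: pd.DataFrame, value_column: str = "tfhi", threshold: float | None = None
) -> StratificationResult:
    """Threshold-optimized survival stratification of a biomarker.

    With ``threshold=None`` the c-index-optimal cutoff is searched
    exhaustively; otherwise the given cutoff is applied. Returns the KM curves
    of the two groups, their median OS and difference, and the univariate Cox
    hazard ratio of the high group with 95% CI and Wald p.
    """
    if value_column == "tfhi":
        validate_cohort(table)
    elif value_column not in table.columns:
        raise ValueError(f"cohort table lacks column {value_column!r}")
    values = table[value_column].to_numpy(dtype=np.float64)
    t = table["os_days"].to_numpy(dtype=np.float64)
    e = table["event"].to_numpy(dtype=int)
    if e.sum() == 0:
        raise ValueError("cohort has zero events; stratification refused")
    if threshold is None:
        threshold, c = optimal_threshold(values, t, e)
    else:
        c = harrell_cindex((values > threshold).astype(float), t, e)
    high = values > threshold
    cox = cox_fit(pd.DataFrame({"high": high.astype(float)}), t, e)
    km_high = kaplan_meier(t[high], e[high])
    km_low = kaplan_meier(t[~high], e[~high])
    mh, ml = km_high.median(), km_low.median()
    delta = abs(mh - ml) if (mh is not None and ml is not None) else None
    return StratificationResult(
        threshold=float(threshold),
        c_index=float(c),
        hazard_ratio=cox.hazard_ratios["high"],
        ci95=(cox.ci_lower["high"], cox.ci_upper["high"]),
        wald_p=cox.wald_p["high"],
        km_high=km_high,
        km_low=km_low,
        median_high=mh,
        median_low=ml,
        delta_os_days=delta,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )


def incremental_cox(
    table: pd.DataFrame, impute: str = "modal", seed: int | None = None
) -> dict[str, CoxModelResult]:
    """Fit the incremental model tiers, each with and without TFHI."""
    results = {}
    for tier in ("clinical", "clinical+perfusion", "clinical+perfusion+volumetric"):
        for with_tfhi in (False, True):
            key = f"{tier}{'+tfhi' if with_tfhi else ''}"
            design = encode_covariates(
                table, tier=tier, include_tfhi=with_tfhi, impute=impute, seed=seed
            )
            results[key] = cox_fit(design, table["os_days"], table["event"])
    return results


def correlate_ratios(tfhi_values, cet_edema_values) -> float:
    """Pearson correlation between TFHI and the CET/edema ratio."""
    x = np.asarray(tfhi_values, dtype=np.float64)
    y = np.asarray(cet_edema_values, dtype=np.float64)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the ratio vectors")
    return float(stats.pearsonr(x, y).statistic)
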