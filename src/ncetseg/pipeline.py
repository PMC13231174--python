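"""Per-case and cohort-level orchestration.

``run_case`` executes the per-case pipeline in order — features → NLSVFMM →
boundary cleanup → statistical/practical validation → TFHI — and emits a
machine-readable case report plus the output label map (code 3 = nCET).
``run_cohort`` aggregates a per-patient table and runs the survival stage:
c-index-optimal stratification and the incremental Cox tiers.

Both are deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULT_CONFIG, deep_merge
from .imaging_io import (
    AnatomyLabelMap,
    IntensityVolume,
    check_same_grid,
    read_labelmap,
    read_volume,
    write_labelmap,
)
from .nlsvfmm import NlsvfmmParams, build_features, classify, fit, nonlocal_weights
from .postprocess import CleanupParams, EdemaSplit, remove_boundary_islands
from .survival import incremental_cox, stratify, validate_cohort
from .tfhi import compute_tfhi
from .validation import validate_case


@dataclass
class CaseReport:
    """Everything needed to reproduce and audit one case."""

    input_hashes: dict
    nlsvfmm: dict
    removal_report: list
    validation: dict
    biomarkers: dict
    config: dict
    seed: int
    software_version: str = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Tag exceptions with the pipeline stage they came from."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except Exception as err:
            raise type(err)(f"[stage: {name}] {err}") from err

    return ctx()


def run_case_arrays(
    t2: IntensityVolume,
    flair: IntensityVolume,
    anatomy: AnatomyLabelMap,
    config: dict | None = None,
    input_hashes: dict | None = None,
) -> tuple[CaseReport, EdemaSplit]:
    """Run the per-case pipeline on in-memory volumes."""
    cfg = deep_merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])

    with _stage("grid-check"):
        check_same_grid([t2, flair, anatomy])
    edema = anatomy.edema_mask
    if not edema.any():
        raise ValueError("[stage: grid-check] anatomy has an empty edema label")

    with _stage("features"):
        features = build_features(t2, flair, edema)

    ncfg = dict(cfg["nlsvfmm"])
    params = NlsvfmmParams(init_seed=seed, **ncfg)
    with _stage("nlsvfmm"):
        weights = (
            nonlocal_weights(features, params)
            if params.mixing_mode == "nonlocal_spatially_varying" and params.beta > 0
            else None
        )
        fit_result = fit(features, weights=weights, params=params)
        split = classify(fit_result, features)

    ccfg = dict(cfg["cleanup"])
    cleanup_enabled = ccfg.pop("enabled", True)
    if cleanup_enabled:
        with _stage("cleanup"):
            split = remove_boundary_islands(
                split,
                edema,
                anatomy.cet_mask,
                anatomy.spacing,
                CleanupParams(**ccfg),
                lesion_mask=anatomy.lesion_mask,
            )

    vcfg = cfg["validation"]
    with _stage("validation"):
        report = validate_case(
            split,
            t2,
            flair,
            alpha=vcfg["alpha"],
            delta_i_cutoff=vcfg["delta_i_cutoff"],
            summary=vcfg["summary"],
        )

    with _stage("tfhi"):
        biomarkers = compute_tfhi(split, anatomy)

    case_report = CaseReport(
        input_hashes=input_hashes or {},
        nlsvfmm={
            "converged": fit_result.converged,
            "n_iter": fit_result.n_iter,
            "objective_first": fit_result.objective_trace[0],
            "objective_last": fit_result.objective_trace[-1],
            "objective_trace": fit_result.objective_trace,
            "ncet_class_index": fit_result.ncet_class_index,
            "class_flair_means_raw": fit_result.flair_means_raw.tolist(),
            "flags": split.flags,
            "bandwidth": weights.bandwidth if weights is not None else None,
        },
        removal_report=split.removal_report,
        validation=report.to_dict(),
        biomarkers=biomarkers.to_dict(),
        config=cfg,
        seed=seed,
    )
    return case_report, split


def run_case(
    t2_path: str | Path,
    flair_path: str | Path,
    anatomy_path: str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> tuple[CaseReport, EdemaSplit]:
    """Run the per-case pipeline from NIfTI files, optionally writing outputs.

    When ``out_dir`` is given, writes ``labels_ncet.nii.gz`` (code 3 = nCET)
    and ``case_report.json`` there.
    """
    with _stage("io"):
        t2 = read_volume(t2_path, name="t2")
        flair = read_volume(flair_path, name="flair")
        anatomy = read_labelmap(anatomy_path, name="anatomy")
    hashes = {
        "t2": _sha256(t2_path),
        "flair": _sha256(flair_path),
        "anatomy": _sha256(anatomy_path),
    }
    report, split = run_case_arrays(t2, flair, anatomy, config, input_hashes=hashes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with _stage("io"):
            write_labelmap(split, anatomy, out_dir / "labels_ncet.nii.gz")
            report.to_json(out_dir / "case_report.json")
    return report, split


def run_cohort(
    cohort: pd.DataFrame | str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cohort-level survival analysis from a per-patient table (or CSV path).

    Runs the c-index-optimal TFHI stratification, the comparator CET/edema
    stratification and Pearson correlation when the column is present, and the
    incremental Cox tiers when the covariates are present. A cohort of fewer
    than 10 patients is analyzed but flagged as unreliable.
    """
    cfg = deep_merge(DEFAULT_CONFIG, config or {})
    if not isinstance(cohort, pd.DataFrame):
        cohort = pd.read_csv(cohort)
    validate_cohort(cohort)
    results: dict = {"n": len(cohort), "warnings": []}
    if len(cohort) < 10:
        results["warnings"].append("cohort below n=10; estimates unreliable")

    with _stage("stratify"):
        strat = stratify(cohort)
    results["tfhi_stratification"] = strat.to_dict()

    if "cet_edema_ratio" in cohort.columns:
        with _stage("stratify"):
            comp = stratify(cohort, value_column="cet_edema_ratio")
        results["cet_edema_stratification"] = comp.to_dict()
        from .survival import correlate_ratios

        results["pearson_tfhi_vs_cet_edema"] = correlate_ratios(
            cohort["tfhi"], cohort["cet_edema_ratio"]
        )

    scfg = cfg["survival"]
    from .survival import TIERS

    if all(c in cohort.columns for c in TIERS["full"]):
        with _stage("coxfit"):
            tiers = incremental_cox(
                cohort, impute=scfg["impute"], seed=int(cfg["seed"])
            )
        results["cox_tiers"] = {k: v.to_dict() for k, v in tiers.items()}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        Path(out_dir, "cohort_results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True, default=_jsonable)
        )
    return results
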