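import numpy as np
import pytest

from ncetseg import (
    CleanupParams,
    NlsvfmmParams,
    PhantomConfig,
    build_features,
    classify,
    fit,
    generate_phantom,
    nonlocal_weights,
    remove_boundary_islands,
)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom (seed 1): 64^3, 1 mm, 3-SD FLAIR separation."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def fitted_case(phantom_case):
    """Full segmentation of the session phantom, raw and cleaned."""
    case = phantom_case
    features = build_features(case.t2, case.flair, case.anatomy.edema_mask)
    params = NlsvfmmParams()
    weights = nonlocal_weights(features, params)
    fit_result = fit(features, weights=weights, params=params)
    raw_split = classify(fit_result, features)
    cleaned = remove_boundary_islands(
        raw_split,
        case.anatomy.edema_mask,
        case.anatomy.cet_mask,
        case.anatomy.spacing,
        CleanupParams(),
        lesion_mask=case.anatomy.lesion_mask,
    )
    return {
        "case": case,
        "features": features,
        "params": params,
        "weights": weights,
        "fit": fit_result,
        "raw_split": raw_split,
        "cleaned_split": cleaned,
    }
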