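"""Non-local spatially varying finite mixture model (NLSVFMM) for edema
sub-segmentation.

The peritumoral edema of a glioblastoma is split into two classes from the
bivariate (T2, FLAIR) intensity of each voxel: a putative non-contrast-
enhancing tumor (nCET) class, with relatively *lower* FLAIR signal, and
vasogenic edema, hyperintense on both sequences. The model is a two-component
bivariate Gaussian mixture whose mixing proportions vary per voxel and are
regularized by non-local, patch-similarity weights: voxels whose FLAIR
patches look alike are pushed toward similar mixing proportions.

Fitting is by EM. Writing :math:`N_k(x) = N(x;\\mu_k,\\Sigma_k)` and
:math:`w_{ij}` for the non-local weights, one iteration performs

- E-step:  :math:`r_{ik} \\propto \\pi_{ik} N_k(x_i)`
- M-step:  weighted MLE of :math:`\\mu_k, \\Sigma_k` (with a variance floor)
- mixing:  :math:`\\pi_{ik} \\leftarrow (r_{ik} + \\beta \\sum_j w_{ij} r_{jk})
  / (1 + \\beta \\sum_j w_{ij})`

and the penalized objective

.. math::

   J = \\sum_i \\log \\sum_k \\pi_{ik} N_k(x_i)
       - \\frac{\\beta}{2} \\sum_{ij} w_{ij} \\sum_k (\\pi_{ik}-\\pi_{jk})^2

is tracked and kept non-decreasing (the mixing step is damped toward the
previous mixing field on the rare occasions the closed-form update would
decrease J). With ``beta = 0`` or ``mixing_mode = "global"`` the model reduces
to a standard bivariate Gaussian mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from sklearn.cluster import KMeans

from .imaging_io import IntensityVolume, check_same_grid
from .postprocess import EdemaSplit

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class FeatureField:
    """Per-voxel (T2, FLAIR) features inside the edema mask, z-scored in-mask.

    ``X[:, 0]`` is T2 and ``X[:, 1]`` is FLAIR. ``flat_index`` maps each row to
    its raveled voxel index; ``channel_stats`` stores the in-mask raw mean/SD
    per channel so fitted class means can be mapped back to scanner units.
    """

    X: np.ndarray
    mask: np.ndarray
    flat_index: np.ndarray
    spacing: np.ndarray
    channel_stats: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]

    def to_volume(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter per-row values back into a 3D volume."""
        out = np.full(self.mask.shape, fill, dtype=np.asarray(values).dtype)
        out.ravel()[self.flat_index] = values
        return out


@dataclass
class NlsvfmmParams:
    """Tunable parameters of the mixture model (K is fixed at 2)."""

    patch_radius: int = 1       # 3^3 patches
    search_radius: int = 2      # 5^3 search window
    bandwidth: float | None = None  # None -> median in-window patch distance
    beta: float = 1.0
    max_iter: int = 100
    tol: float = 1e-5
    init_seed: int = 0
    mixing_mode: Literal["nonlocal_spatially_varying", "global"] = "nonlocal_spatially_varying"
    variance_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.patch_radius < 0 or self.search_radius < 1:
            raise ValueError("invalid patch/search radius")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth h must be > 0")
        if self.mixing_mode not in ("nonlocal_spatially_varying", "global"):
            raise ValueError(f"unknown mixing_mode {self.mixing_mode!r}")


@dataclass
class NonlocalWeights:
    """Sparse symmetric patch-similarity weights between in-mask voxels."""

    matrix: sp.csr_matrix
    bandwidth: float


@dataclass
class MixtureFit:
    """Fitted NLSVFMM state."""

    means: np.ndarray            # (2, 2) in z-scored feature units
    covariances: np.ndarray      # (2, 2, 2)
    mixing: np.ndarray           # (n, 2) per-voxel mixing proportions
    responsibilities: np.ndarray  # (n, 2)
    objective_trace: list[float]
    converged: bool
    n_iter: int
    ncet_class_index: int
    flair_means_raw: np.ndarray  # (2,) class FLAIR means in scanner units
    flair_tie: bool = False


def build_features(
    t2: IntensityVolume, flair: IntensityVolume, edema_mask: np.ndarray
) -> FeatureField:
    """Extract z-scored (T2, FLAIR) features for every edema voxel.

    A channel that is constant inside the mask (SD = 0) is set to all zeros
    with a warning rather than failing.
    """
    check_same_grid([t2, flair])
    edema_mask = np.asarray(edema_mask, dtype=bool)
    if edema_mask.shape != t2.shape:
        raise ValueError("edema mask is not on the image grid")
    if not edema_mask.any():
        raise ValueError("empty edema mask")
    flat_index = np.flatnonzero(edema_mask.ravel())
    X = np.empty((flat_index.size, 2))
    stats = {}
    for c, (label, vol) in enumerate([("t2", t2), ("flair", flair)]):
        vals = vol.data.ravel()[flat_index]
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0.0:
            warnings.warn(f"constant {label.upper()} channel inside the edema mask")
            X[:, c] = 0.0
        else:
            X[:, c] = (vals - mu) / sd
        stats[label] = {"mean": mu, "sd": sd}
    return FeatureField(
        X=X,
        mask=edema_mask,
        flat_index=flat_index,
        spacing=np.asarray(t2.spacing, dtype=np.float64),
        channel_stats=stats,
    )


def _box_sum(vol, patch_radius):
    """Cube-window sum with zero padding at the volume border."""
    size = 2 * patch_radius + 1
    return ndimage.uniform_filter(vol, size=size, mode="constant", cval=0.0) * size**3


def nonlocal_weights(features: FeatureField, params: NlsvfmmParams) -> NonlocalWeights:
    """Patch-similarity weights ``w_ij = exp(-||P_i - P_j||^2 / h^2)``.

    Patches are cubes of the z-scored FLAIR channel (side ``2*patch_radius+1``)
    and pairs (i, j) range over in-mask voxels with j inside the cubic search
    window of i (center excluded). Patch positions where either patch falls
    outside the mask contribute zero to the squared distance, which keeps the
    weights exactly symmetric, including at volume borders. With
    ``bandwidth=None`` the scale h is set to the median in-window patch
    distance (auto-bandwidth).
    """
    if params.patch_radius > params.search_radius:
        raise ValueError("patch_radius must not exceed search_radius")
    mask = features.mask
    V = features.to_volume(features.X[:, 1])  # z-scored FLAIR, 0 outside mask
    M = mask.astype(np.float64)
    row_id = np.full(mask.shape, -1, dtype=np.int64)
    row_id[mask] = np.arange(features.n_voxels)

    s = params.search_radius
    offsets = [
        (dx, dy, dz)
        for dx in range(-s, s + 1)
        for dy in range(-s, s + 1)
        for dz in range(-s, s + 1)
        if (dx, dy, dz) > (0, 0, 0)  # half-space; mirror added via transpose
    ]

    rows, cols, dists = [], [], []
    shape = mask.shape
    for d in offsets:
        src = tuple(slice(max(0, -di), sh - max(0, di)) for di, sh in zip(d, shape))
        dst = tuple(slice(max(0, di), sh + min(0, di)) for di, sh in zip(d, shape))
        # E(q) = M(q) M(q+d) (V(q) - V(q+d))^2 placed at position q
        E = np.zeros(shape)
        pairvalid = np.zeros(shape)
        pairvalid[src] = M[src] * M[dst]
        E[src] = pairvalid[src] * (V[src] - V[dst]) ** 2
        D = _box_sum(E, params.patch_radius)
        # entries: i in mask with i+d in mask
        imask = np.zeros(shape, dtype=bool)
        imask[src] = mask[src] & mask[dst]
        i_rows = row_id[imask]
        jj = np.zeros(shape, dtype=np.int64)
        jj[src] = row_id[dst]
        j_cols = jj[imask]
        rows.append(i_rows)
        cols.append(j_cols)
        dists.append(D[imask])

    n = features.n_voxels
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        dists = np.concatenate(dists)
    else:  # pragma: no cover - degenerate single-voxel mask
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
        dists = np.empty(0)

    if params.bandwidth is not None:
        h = float(params.bandwidth)
    else:
        h = float(np.median(np.sqrt(dists))) if dists.size else 1.0
        if h <= 0:
            h = 1.0
    vals = np.exp(-dists / h**2)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    W = W + W.T
    return NonlocalWeights(matrix=W, bandwidth=h)


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a bivariate Gaussian, closed form."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    d0 = X[:, 0] - mean[0]
    d1 = X[:, 1] - mean[1]
    quad = (c * d0 * d0 - 2 * b * d0 * d1 + a * d1 * d1) / det
    return -0.5 * (quad + np.log(det)) - _LOG2PI


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Clip covariance eigenvalues from below (variance floor)."""
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= floor:
        return cov
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _objective(X, means, covs, pi, beta, W) -> float:
    logN = np.column_stack([_log_gaussian(X, means[k], covs[k]) for k in range(2)])
    with np.errstate(divide="ignore"):
        mix = np.log(np.maximum(pi, 1e-300)) + logN
    m = mix.max(axis=1)
    ll = float(np.sum(m + np.log(np.exp(mix - m[:, None]).sum(axis=1))))
    if beta > 0 and W is not None:
        deg = np.asarray(W.sum(axis=1)).ravel()
        pen = 0.0
        for k in range(2):
            p = pi[:, k]
            pen += float(p @ (deg * p) - p @ (W @ p))
        ll -= beta * pen  # equals (beta/2) * sum_ij w_ij (pi_ik - pi_jk)^2
    return ll


def _init_responsibilities(X: np.ndarray, seed: int, swap: bool = False) -> np.ndarray:
    """Hard k-means (K=2) initialization on the FLAIR channel."""
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(X[:, [1]])
    if swap:
        labels = 1 - labels
    r = np.zeros((X.shape[0], 2))
    r[np.arange(X.shape[0]), labels] = 1.0
    return r


def fit(
    features: FeatureField | np.ndarray,
    weights: NonlocalWeights | None = None,
    params: NlsvfmmParams | None = None,
    init_swap: bool = False,
) -> MixtureFit:
    """Fit the two-class mixture by EM.

    ``features`` may be a :class:`FeatureField` or a plain (n, 2) array (the
    latter is convenient for fitting arbitrary samples in ``global`` mode).
    ``init_swap`` permutes the k-means initialization classes; the final split
    is invariant to it.
    """
    params = params or NlsvfmmParams()
    if isinstance(features, FeatureField):
        X = features.X
        stats = features.channel_stats
    else:
        X = np.asarray(features, dtype=np.float64)
        stats = None
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 2K = 4 voxels to fit the mixture")

    nonlocal_mode = params.mixing_mode == "nonlocal_spatially_varying"
    W = None
    wsum = None
    if nonlocal_mode and params.beta > 0:
        if weights is None:
            if not isinstance(features, FeatureField):
                raise ValueError("non-local mode on a raw array requires precomputed weights")
            weights = nonlocal_weights(features, params)
        W = weights.matrix
        wsum = np.asarray(W.sum(axis=1)).ravel()

    r = _init_responsibilities(X, params.init_seed, swap=init_swap)
    Nk = r.sum(axis=0)
    means = (r.T @ X) / Nk[:, None]
    covs = np.empty((2, 2, 2))
    for k in range(2):
        d = X - means[k]
        covs[k] = _floor_cov((d.T * r[:, k]) @ d / Nk[k], params.variance_floor)
    pi = np.broadcast_to(Nk / n, (n, 2)).copy()

    trace: list[float] = [_objective(X, means, covs, pi, params.beta if W is not None else 0.0, W)]
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # E-step
        logN = np.column_stack([_log_gaussian(X, means[k], covs[k]) for k in range(2)])
        with np.errstate(divide="ignore"):
            logr = np.log(np.maximum(pi, 1e-300)) + logN
        logr -= logr.max(axis=1, keepdims=True)
        r = np.exp(logr)
        r /= r.sum(axis=1, keepdims=True)

        # M-step: class parameters
        Nk = np.maximum(r.sum(axis=0), 1e-12)
        means = (r.T @ X) / Nk[:, None]
        for k in range(2):
            d = X - means[k]
            covs[k] = _floor_cov((d.T * r[:, k]) @ d / Nk[k], params.variance_floor)

        # mixing update
        if not nonlocal_mode:
            pi_cand = np.broadcast_to(Nk / n, (n, 2)).copy()
        elif W is None:  # beta == 0
            pi_cand = r.copy()
        else:
            pi_cand = (r + params.beta * (W @ r)) / (1.0 + params.beta * wsum)[:, None]

        beta_eff = params.beta if W is not None else 0.0
        obj = _objective(X, means, covs, pi_cand, beta_eff, W)
        prev = trace[-1]
        if obj < prev - 1e-12:
            # damped step toward the previous mixing field; the class-parameter
            # M-step alone cannot decrease J, so t -> 0 restores monotonicity
            t = 0.5
            best_obj = _objective(X, means, covs, pi, beta_eff, W)
            best_pi = pi
            while t > 1e-6:
                cand = pi + t * (pi_cand - pi)
                o = _objective(X, means, covs, cand, beta_eff, W)
                if o >= best_obj:
                    best_obj, best_pi = o, cand
                    break
                t *= 0.5
            pi, obj = best_pi, best_obj
        else:
            pi = pi_cand
        trace.append(obj)

        if abs(obj - prev) <= params.tol * (abs(prev) + 1e-12):
            converged = True
            break

    # final E-step so responsibilities match the returned parameters
    logN = np.column_stack([_log_gaussian(X, means[k], covs[k]) for k in range(2)])
    with np.errstate(divide="ignore"):
        logr = np.log(np.maximum(pi, 1e-300)) + logN
    logr -= logr.max(axis=1, keepdims=True)
    r = np.exp(logr)
    r /= r.sum(axis=1, keepdims=True)

    # nCET = class with lower mean FLAIR in scanner units
    if stats is not None and stats["flair"]["sd"] > 0:
        flair_raw = means[:, 1] * stats["flair"]["sd"] + stats["flair"]["mean"]
    else:
        flair_raw = means[:, 1].copy()
    tie = bool(abs(flair_raw[0] - flair_raw[1]) < 1e-9)
    ncet_idx = 0 if tie else int(np.argmin(flair_raw))

    return MixtureFit(
        means=means,
        covariances=covs,
        mixing=pi,
        responsibilities=r,
        objective_trace=trace,
        converged=converged,
        n_iter=it,
        ncet_class_index=ncet_idx,
        flair_means_raw=flair_raw,
        flair_tie=tie,
    )


def classify(fit_result: MixtureFit, features: FeatureField) -> EdemaSplit:
    """Hard-assign voxels by maximum responsibility into an edema split.

    The nCET mask is the class with the lower (scanner-unit) mean FLAIR;
    responsibility ties go deterministically to class 0 and are flagged.
    """
    r = fit_result.responsibilities
    ties = np.abs(r[:, 0] - r[:, 1]) < 1e-9
    hard = np.argmax(r, axis=1)
    hard[ties] = 0
    ncet_rows = hard == fit_result.ncet_class_index
    ncet_mask = features.to_volume(ncet_rows, fill=False)
    vasog_mask = features.mask & ~ncet_mask
    flags = {}
    if ties.any():
        flags["responsibility_ties"] = int(ties.sum())
    if fit_result.flair_tie:
        flags["flair_mean_tie"] = True
    split = EdemaSplit(ncet_mask=ncet_mask, vasogenic_mask=vasog_mask, flags=flags)
    split.check_partition(features.mask)
    return split
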