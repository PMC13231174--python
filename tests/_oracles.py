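"""Independent reference implementations used only to check the package.

Each oracle is written directly from first principles (textbook equations,
brute-force enumeration) and deliberately shares no code with ncetseg.
"""

import numpy as np
from scipy.stats import multivariate_normal


def textbook_gmm_em(X, init_labels, max_iter=500, tol=1e-12):
    """Plain two-component bivariate Gaussian mixture EM (global weights)."""
    X = np.asarray(X, float)
    n = len(X)
    r = np.zeros((n, 2))
    r[np.arange(n), init_labels] = 1.0
    ll_old = -np.inf
    for _ in range(max_iter):
        nk = r.sum(axis=0)
        pis = nk / n
        mus = [(r[:, k] @ X) / nk[k] for k in range(2)]
        covs = []
        for k in range(2):
            d = X - mus[k]
            covs.append((d.T * r[:, k]) @ d / nk[k])
        dens = np.column_stack(
            [pis[k] * multivariate_normal.pdf(X, mus[k], covs[k]) for k in range(2)]
        )
        tot = dens.sum(axis=1)
        ll = float(np.log(tot).sum())
        r = dens / tot[:, None]
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            break
        ll_old = ll
    return {"means": np.array(mus), "covs": np.array(covs), "weights": pis, "loglik": ll, "resp": r}


def bfs_components_26(mask):
    """Connected components under 26-connectivity by explicit BFS."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    nbrs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    current = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = [start]
        labels[start] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in nbrs:
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < shape[0]
                    and 0 <= p[1] < shape[1]
                    and 0 <= p[2] < shape[2]
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = current
                    queue.append(p)
    return labels, current


def brute_force_band(edema_mask, spacing, band_width_mm, lesion_mask=None):
    """Band by all-pairs mm distance from edema voxels to non-lesion voxels."""
    edema_mask = np.asarray(edema_mask, bool)
    lesion = edema_mask if lesion_mask is None else np.asarray(lesion_mask, bool)
    spacing = np.asarray(spacing, float)
    outside = np.argwhere(~lesion) * spacing
    band = np.zeros(edema_mask.shape, bool)
    for idx in np.argwhere(edema_mask):
        d = np.sqrt(((outside - idx * spacing) ** 2).sum(axis=1)).min()
        band[tuple(idx)] = d <= band_width_mm
    return band


def brute_force_cindex(risk, t, e):
    """Harrell c-index by a plain double loop over ordered pairs."""
    num = den = 0.0
    n = len(t)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (t[i] < t[j] and e[i]) or (t[i] == t[j] and e[i] and not e[j])
            if not usable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    return num / den


def grid_search_cox_binary(x, t, e, grid=None):
    """1-D maximizer of the Cox partial likelihood for a binary covariate.

    Assumes no tied event times (partial likelihood in its basic form).
    """
    x = np.asarray(x, float)
    t = np.asarray(t, float)
    e = np.asarray(e, bool)
    if grid is None:
        grid = np.linspace(-3, 3, 6001)

    order = np.argsort(t)
    x_s, e_s = x[order], e[order]
    # at-risk sums computed from the back
    def neg_pl(beta):
        eta = beta * x_s
        exps = np.exp(eta)
        # cumulative sum of risk set from the end
        risk = np.cumsum(exps[::-1])[::-1]
        return -float(np.sum((eta - np.log(risk))[e_s]))

    vals = [neg_pl(b) for b in grid]
    return float(grid[int(np.argmin(vals))])


def rank_sum_u(a, b):
    """Mann-Whitney U of sample a versus b via midranks, from the definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    allv = np.concatenate([a, b])
    order = allv.argsort()
    ranks = np.empty_like(allv)
    ranks[order] = np.arange(1, len(allv) + 1, dtype=float)
    # midranks for ties
    for v in np.unique(allv):
        sel = allv == v
        ranks[sel] = ranks[sel].mean()
    r1 = ranks[: len(a)].sum()
    return r1 - len(a) * (len(a) + 1) / 2.0
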