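"""Mask-initialised GrabCut.

Iterated graph cut over colour Gaussian-mixture models: per-iteration
foreground/background GMMs are refit on the current labelling, pixel unaries
are negative GMM log-likelihoods, and the binary labelling is solved exactly
as a minimum s-t cut on a 4-connected grid (contrast-sensitive smoothness
term), via ``scipy.sparse.csgraph.maximum_flow`` with a residual-graph
reachability pass to recover the cut partition.  Definite seed pixels are
pinned with infinite-capacity terminal links.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import maximum_flow, breadth_first_order
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

# capacity scaling: float energies -> integer capacities for maximum_flow
_SCALE = 100.0
_HARD = 10_000_000  # pin capacity; far above any achievable cut contribution
_MAX_GMM_SAMPLES = 4000


def _fit_gmm(z: np.ndarray, n_components: int) -> GaussianMixture:
    n_components = max(1, min(n_components, len(z)))
    if len(z) > _MAX_GMM_SAMPLES:  # deterministic thinning for speed
        step = len(z) // _MAX_GMM_SAMPLES + 1
        zfit = z[::step]
    else:
        zfit = z
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         reg_covar=1.0, max_iter=30, random_state=0)
    with warnings.catch_warnings():
        # a colour model refit mid-iteration need not converge fully
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(zfit)
    return gm


def _pairwise_terms(z_img: np.ndarray, gamma: float):
    """4-connectivity contrast weights; returns (u, v, w) edge arrays."""
    h, w_ = z_img.shape[:2]
    idx = np.arange(h * w_).reshape(h, w_)
    du = [(idx[:, :-1], idx[:, 1:], z_img[:, :-1] - z_img[:, 1:]),
          (idx[:-1, :], idx[1:, :], z_img[:-1, :] - z_img[1:, :])]
    us, vs, sq = [], [], []
    for a, b, d in du:
        us.append(a.ravel())
        vs.append(b.ravel())
        sq.append((d ** 2).sum(axis=-1).ravel())
    u = np.concatenate(us)
    v = np.concatenate(vs)
    ssq = np.concatenate(sq)
    beta = 1.0 / (2.0 * max(ssq.mean(), 1e-9))
    w = gamma * np.exp(-beta * ssq)
    return u, v, w


def grabcut(
    rgb: np.ndarray,
    seed: np.ndarray,
    iterations: int = 5,
    n_components: int = 5,
    gamma: float = 50.0,
) -> np.ndarray:
    """Run iterated GMM + graph-cut segmentation.

    ``seed`` is the 4-level mask with levels 0 definite background, 1 definite
    foreground, 2 probable background, 3 probable foreground.  Returns a
    boolean foreground mask of the same shape.
    """
    h, w_ = seed.shape
    n = h * w_
    z_img = rgb.astype(np.float64)
    z = z_img.reshape(n, 3)
    seed_flat = seed.reshape(n)

    def_fg = seed_flat == 1
    def_bg = seed_flat == 0
    alpha = (seed_flat == 1) | (seed_flat == 3)  # current FG labelling

    pu, pv, pw = _pairwise_terms(z_img, gamma)
    pw_int = np.maximum((pw * _SCALE).astype(np.int32), 0)
    source, sink = n, n + 1

    for _ in range(iterations):
        if not alpha.any() or alpha.all():
            break
        fg_gmm = _fit_gmm(z[alpha], n_components)
        bg_gmm = _fit_gmm(z[~alpha], n_components)
        d_fg = -fg_gmm.score_samples(z)  # cost of labelling a pixel FG
        d_bg = -bg_gmm.score_samples(z)
        d_fg = np.clip(d_fg, 0.0, 1e4)
        d_bg = np.clip(d_bg, 0.0, 1e4)

        cap_src = (d_bg * _SCALE).astype(np.int32)  # cut when pixel -> BG side
        cap_snk = (d_fg * _SCALE).astype(np.int32)  # cut when pixel -> FG side
        cap_src[def_fg] = _HARD
        cap_snk[def_fg] = 0
        cap_snk[def_bg] = _HARD
        cap_src[def_bg] = 0

        rows = np.concatenate([pu, pv, np.full(n, source), np.arange(n)])
        cols = np.concatenate([pv, pu, np.arange(n), np.full(n, sink)])
        data = np.concatenate([pw_int, pw_int, cap_src, cap_snk])
        keep = data > 0
        graph = sparse.csr_matrix(
            (data[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2))

        res = maximum_flow(graph, source, sink)
        residual = graph - res.flow
        residual.data = (residual.data > 0).astype(np.int32)
        residual.eliminate_zeros()
        reach = breadth_first_order(residual, source, directed=True,
                                    return_predecessors=False)
        new_alpha = np.zeros(n, dtype=bool)
        new_alpha[reach[reach < n]] = True
        new_alpha[def_fg] = True
        new_alpha[def_bg] = False
        if (new_alpha == alpha).all():
            alpha = new_alpha
            break
        alpha = new_alpha

    return alpha.reshape(h, w_)
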