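"""PLS association between spatial gene expression and an effect map.

The samples x genes expression matrix (column-standardized) is regressed
onto the meta-analytic z-map sampled at the expression sample locations
(PLS1: the first-component weight vector is proportional to X'y).
Component significance uses variogram-matched spatial surrogate maps —
permutations of the response smoothed and rescaled so their empirical
variogram matches the original's, preserving spatial autocorrelation —
and per-gene reliability uses bootstrap z-scores (weight / bootstrap SE)
with Bonferroni selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .synthgen import knn_smooth_matrix

__all__ = [
    "PlsModel",
    "SurrogateSet",
    "sample_map_at_locations",
    "pls_fit",
    "empirical_variogram",
    "generate_surrogates",
    "component_significance",
    "bootstrap_gene_scores",
]


@dataclass
class PlsModel:
    """Deflation-based PLS with a single response.

    ``expl_var[k]`` is the incremental share of response variance
    explained by component k (R² of y on scores 1..k+1 minus on 1..k).
    """

    weights: np.ndarray      # genes x components (unit-norm columns)
    scores: np.ndarray       # samples x components
    expl_var: np.ndarray     # per component, in [0, 1]
    perm_p: np.ndarray | None = None


@dataclass
class SurrogateSet:
    """Variogram-matched surrogate responses (n_surr x samples)."""

    maps: np.ndarray
    bandwidths: np.ndarray
    seed: int


def sample_map_at_locations(
    zmap: np.ndarray,
    affine: np.ndarray,
    sample_meta: pd.DataFrame,
):
    """Nearest-voxel map values at sample MNI coordinates, z-scored.

    Samples outside the grid are dropped with a warning; standardization
    happens after dropping.  Returns ``(y, kept_mask)`` aligned with
    ``sample_meta`` rows.  A constant map raises (zero variance).
    """
    coords = sample_meta[["x", "y", "z"]].to_numpy(dtype=float)
    inv = np.linalg.inv(affine)
    ijk = np.rint(coords @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.array(zmap.shape)
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not inside.all():
        warnings.warn(f"{(~inside).sum()} samples outside the map grid dropped")
    vals = zmap[tuple(ijk[inside].T)]
    if len(vals) < 2 or np.std(vals) == 0:
        raise ValueError("map values are constant at the sample locations")
    y = (vals - vals.mean()) / vals.std()
    return y, inside


def pls_fit(X: np.ndarray, y: np.ndarray, n_comp: int = 1) -> PlsModel:
    """Deflation PLS for a single response.

    Component 1's weight vector is exactly X'y normalized to unit length;
    subsequent components repeat on the deflated X.  Columns of X must be
    standardized and non-constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be samples x genes aligned with y")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance gene columns must be removed first")
    rank = np.linalg.matrix_rank(X) if min(X.shape) <= 200 else min(X.shape)
    if n_comp > rank:
        raise ValueError("n_comp exceeds the rank of X")

    n, g = X.shape
    Xd = X.copy()
    weights = np.zeros((g, n_comp))
    scores = np.zeros((n, n_comp))
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    r2 = [0.0]
    x_scale = np.linalg.norm(X) * max(np.linalg.norm(y), 1.0)
    for k in range(n_comp):
        w = Xd.T @ y
        norm = np.linalg.norm(w)
        if norm <= 1e-12 * x_scale:
            # response orthogonal to the deflated predictors
            weights[:, k] = 0.0
            scores[:, k] = 0.0
            r2.append(r2[-1])
            continue
        w /= norm
        t = Xd @ w
        weights[:, k] = w
        scores[:, k] = t
        Xd = Xd - np.outer(t, (t @ Xd) / (t @ t))
        # incremental R^2 of y on scores 1..k+1
        S = scores[:, : k + 1]
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), S]), y, rcond=None)
        resid = y - np.column_stack([np.ones(n), S]) @ coef
        r2.append(1.0 - float(resid @ resid) / ss_tot)
    expl = np.diff(np.array(r2))
    return PlsModel(weights=weights, scores=scores, expl_var=np.clip(expl, 0.0, 1.0))


def empirical_variogram(
    y: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 25,
    max_frac: float = 0.25,
):
    """Isotropic empirical semivariogram.

    gamma(b) = mean of (y_i - y_j)^2 / 2 over pairs whose distance falls
    in bin b, for distances up to the ``max_frac`` quantile of all
    pairwise distances.  Returns ``(bin_centers, gamma)``; empty bins get
    NaN.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two points")
    d = pdist(coords)
    if d.max() == 0:
        raise ValueError("all points coincident")
    dy2 = pdist(y[:, None], metric="sqeuclidean")
    dmax = np.quantile(d, max_frac)
    if dmax <= 0:
        dmax = d.max()
    edges = np.linspace(0.0, dmax, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= dmax
    gamma = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = keep & (which == b)
        if sel.any():
            gamma[b] = 0.5 * dy2[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma


def generate_surrogates(
    y: np.ndarray,
    coords: np.ndarray,
    n_surr: int = 1000,
    bandwidths: tuple[int, ...] = (5, 10, 20, 40, 80),
    n_bins: int = 25,
    max_frac: float = 0.25,
    rank_remap: bool = True,
    seed: int = 0,
) -> SurrogateSet:
    """Variogram-matched spatial surrogates of a mapped response.

    Per surrogate: permute y, smooth with a k-nearest-neighbour
    exponential kernel at each candidate bandwidth, fit nonnegative
    (beta, alpha) by least squares so beta*gamma_smooth + alpha tracks the
    target variogram, keep the bandwidth with the smallest SSE, and emit
    sqrt(beta) * smoothed + sqrt(alpha) * permuted noise.  With
    ``rank_remap`` the surrogate's values are remapped onto the original
    multiset, making the amplitude distribution exact.
    """
    if n_surr < 1:
        raise ValueError("n_surr must be >= 1")
    if not bandwidths:
        raise ValueError("bandwidth list must not be empty")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    centers, gamma_t = empirical_variogram(y, coords, n_bins, max_frac)
    valid = ~np.isnan(gamma_t)
    gamma_t = gamma_t[valid]

    smoothers = {k: knn_smooth_matrix(coords, k) for k in bandwidths}
    # pairwise-bin bookkeeping shared by all surrogates
    d = pdist(coords)
    dmax = np.quantile(d, max_frac)
    if dmax <= 0:
        dmax = d.max()
    edges = np.linspace(0.0, dmax, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= dmax

    def vario(v: np.ndarray) -> np.ndarray:
        dy2 = pdist(v[:, None], metric="sqeuclidean")
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = keep & (which == b)
            if sel.any():
                out[b] = 0.5 * dy2[sel].mean()
        return out[valid]

    sorted_y = np.sort(y)
    maps = np.empty((n_surr, n))
    chosen = np.empty(n_surr, dtype=int)
    for s in range(n_surr):
        perm = rng.permutation(y)
        noise = rng.permutation(perm)
        noise = (noise - noise.mean()) / (noise.std() + 1e-12)
        best_sse, best_map, best_k = np.inf, None, bandwidths[0]
        for k in bandwidths:
            sm = smoothers[k] @ perm
            smz = (sm - sm.mean()) / (sm.std() + 1e-12)
            gs = vario(smz)
            gn = vario(noise)
            design = np.column_stack([gs, gn])
            coef, _ = nnls(design, gamma_t)
            fit = design @ coef
            sse = float(((fit - gamma_t) ** 2).sum())
            if sse < best_sse:
                best_sse = sse
                best_k = k
                best_map = np.sqrt(coef[0]) * smz + np.sqrt(coef[1]) * noise
        surr = best_map
        if rank_remap:
            ranks = np.argsort(np.argsort(surr))
            surr = sorted_y[ranks]
        maps[s] = surr
        chosen[s] = best_k
    return SurrogateSet(maps=maps, bandwidths=chosen, seed=seed)


def component_significance(
    X: np.ndarray,
    y: np.ndarray,
    model: PlsModel,
    surrogates: SurrogateSet,
    var_threshold: float = 0.20,
    p_threshold: float = 0.05,
):
    """Permutation p per component from the surrogate null of explained variance.

    perm_p = (1 + #{surrogate expl_var >= observed}) / (1 + n_surr); a
    component is carried forward only if expl_var > ``var_threshold`` and
    perm_p < ``p_threshold``.  Returns ``(perm_p, selected)`` arrays.
    """
    n_comp = model.weights.shape[1]
    n_surr = len(surrogates.maps)
    null = np.zeros((n_surr, n_comp))
    for s, ys in enumerate(surrogates.maps):
        sd = ys.std()
        ys_std = (ys - ys.mean()) / sd if sd > 0 else np.zeros_like(ys)
        null[s] = pls_fit(X, ys_std, n_comp).expl_var
    perm_p = (1.0 + (null >= model.expl_var).sum(axis=0)) / (1.0 + n_surr)
    selected = (model.expl_var > var_threshold) & (perm_p < p_threshold)
    model.perm_p = perm_p
    return perm_p, selected


def bootstrap_gene_scores(
    X: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap z-scores and Bonferroni selection for PLS1 gene weights.

    Samples are resampled with replacement; each resample's PLS1 weight
    vector is sign-aligned to the point estimate (flipped if the dot
    product is negative); boot_se is the SD across resamples; z = weight /
    boot_se with a two-sided normal p, Bonferroni over the number of
    genes.  Degenerate resamples (constant response) are redrawn.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 to estimate a standard error")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, g = X.shape
    w0 = X.T @ y
    w0 /= np.linalg.norm(w0)

    boots = np.empty((n_boot, g))
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.std(yb) > 0:
                break
            redrawn += 1
        Xb = X[idx]
        wb = Xb.T @ yb
        norm = np.linalg.norm(wb)
        if norm > 0:
            wb /= norm
        if wb @ w0 < 0:
            wb = -wb
        boots[b] = wb
    if redrawn:
        warnings.warn(f"{redrawn} degenerate bootstrap resamples redrawn")
    se = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, np.inf * np.sign(w0))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_bonf = np.minimum(1.0, p * g)
    return pd.DataFrame(
        {
            "gene": genes,
            "weight": w0,
            "boot_se": se,
            "z": z,
            "p": p,
            "p_bonf": p_bonf,
            "selected": p_bonf < alpha,
        }
    )
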