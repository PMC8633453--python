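"""Comparison statistics for lesion network maps.

Scalar comparisons (CDF cutoffs, thresholded means, spatial correlations,
the network confidence index, dice, WM-ratio classification), classical
paired tests (Wilcoxon signed-rank, Cohen's d, Friedman), and voxel-wise
permutation inference with max-statistic family-wise error control
(paired sign-flip, two-sample label permutation, and behaviour correlation
with a lesion-size nuisance covariate under the Freedman-Lane scheme).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .mapping import NetworkMap, T_SENTINEL
from .volumes import BinaryMask, TemplateGrid, Volume3D

__all__ = [
    "CanonicalAtlas",
    "NciResult",
    "VoxelwiseTestResult",
    "PairedVoxelwiseResult",
    "cdf_cutoff_values",
    "map_mean_sd",
    "spatial_correlation",
    "nci",
    "dice",
    "wm_ratio",
    "is_pure_wm",
    "wilcoxon_signed_rank",
    "cohens_d_paired",
    "friedman_test",
    "paired_voxelwise_test",
    "two_sample_voxelwise_test",
    "voxelwise_behaviour_correlation",
]

DEFAULT_CDF_PERCENTILES = (10, 20, 50, 80, 90, 95, 99)
PURE_WM_RATIO = 0.9  # strictly greater than this ratio counts as a pure-WM lesion


@dataclass
class CanonicalAtlas:
    """Named template maps scored against lesion network maps."""

    networks: list[tuple[str, Volume3D]]
    exclusions: list[str] = field(default_factory=list)

    @property
    def active(self) -> list[tuple[str, Volume3D]]:
        out = [(n, v) for n, v in self.networks if n not in self.exclusions]
        if len(out) < 2:
            raise ValueError("atlas needs at least 2 networks after exclusions")
        return out


@dataclass
class NciResult:
    winner: str
    winner_sc: float
    losing_scs: list[tuple[str, float]]
    nci: float  # NaN when undefined (non-positive losing mean)
    undefined: bool = False


@dataclass
class VoxelwiseTestResult:
    stat_map: Volume3D
    fwe_p_map: Volume3D
    significant_mask: BinaryMask
    alpha: float
    n_perm: int
    rng_seed: int


@dataclass
class PairedVoxelwiseResult:
    a_gt_b: VoxelwiseTestResult
    b_gt_a: VoxelwiseTestResult


def _values(m) -> np.ndarray:
    return m.values


def _grid(m) -> TemplateGrid:
    return m.grid


# ---------------------------------------------------------------------------
# Scalar map statistics


def cdf_cutoff_values(
    map_: NetworkMap | Volume3D,
    percentiles=DEFAULT_CDF_PERCENTILES,
    domain_mask: BinaryMask | None = None,
) -> np.ndarray:
    """Values of the map's positive-voxel CDF at the given percentiles.

    Zero and negative voxels are masked out before the percentiles are
    taken (linear interpolation), optionally within a GM/WM/whole-brain
    domain mask.
    """
    vals = _values(map_)
    if domain_mask is not None:
        _grid(map_).require_match(domain_mask.grid, "domain mask")
        vals = vals[domain_mask.values]
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("map has no strictly positive voxels in the domain")
    return np.percentile(pos, list(percentiles))


def map_mean_sd(
    map_: NetworkMap | Volume3D,
    z_threshold: float = 0.0,
    domain_mask: BinaryMask | None = None,
) -> tuple[float, float, int]:
    """Mean, SD and count of voxels strictly above ``z_threshold``."""
    vals = _values(map_)
    if domain_mask is not None:
        _grid(map_).require_match(domain_mask.grid, "domain mask")
        vals = vals[domain_mask.values]
    sel = vals[vals > z_threshold]
    if sel.size == 0:
        return (float("nan"), float("nan"), 0)
    return (float(sel.mean()), float(sel.std()), int(sel.size))


def spatial_correlation(
    map_: NetworkMap | Volume3D,
    template: Volume3D,
    domain_mask: BinaryMask | None = None,
) -> float:
    """Pearson correlation between a map and a template over the domain."""
    _grid(map_).require_match(template.grid, "template")
    a = _values(map_)
    b = template.values
    if domain_mask is not None:
        _grid(map_).require_match(domain_mask.grid, "domain mask")
        a, b = a[domain_mask.values], b[domain_mask.values]
    else:
        a, b = a.ravel(), b.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance on one side of the spatial correlation")
    return float(np.corrcoef(a, b)[0, 1])


def nci(
    map_: NetworkMap | Volume3D,
    atlas: CanonicalAtlas,
    domain_mask: BinaryMask | None = None,
) -> NciResult:
    """Winner-take-all network confidence index.

    The winner is the template with the highest spatial correlation; the
    index is the winner's correlation divided by the mean of the losing
    templates' correlations.  A higher NCI means the map matches one
    canonical network specifically rather than all of them diffusely.
    When the losing mean is non-positive the ratio is reported as NaN with
    ``undefined=True`` (the winner is still valid).  Ties go to the first
    template in atlas order.
    """
    scs = [
        (name, spatial_correlation(map_, tpl, domain_mask))
        for name, tpl in atlas.active
    ]
    winner_idx = int(np.argmax([s for _, s in scs]))
    winner, winner_sc = scs[winner_idx]
    losers = [sc for i, sc in enumerate(scs) if i != winner_idx]
    losing_mean = float(np.mean([s for _, s in losers]))
    if losing_mean <= 0:
        return NciResult(winner, winner_sc, losers, float("nan"), undefined=True)
    return NciResult(winner, winner_sc, losers, winner_sc / losing_mean)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a.grid.require_match(b.grid, "mask")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 or nb == 0:
        raise ValueError("dice requires non-empty masks")
    return 2.0 * int((a.values & b.values).sum()) / (na + nb)


def wm_ratio(lesion: BinaryMask, wm: BinaryMask) -> float:
    """Fraction of lesion voxels falling inside the white-matter mask."""
    lesion.grid.require_match(wm.grid, "wm mask")
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    return int((lesion.values & wm.values).sum()) / lesion.n_voxels


def is_pure_wm(lesion: BinaryMask, wm: BinaryMask) -> bool:
    """Pure-WM classification: WM/size ratio strictly greater than 0.9."""
    return wm_ratio(lesion, wm) > PURE_WM_RATIO


# ---------------------------------------------------------------------------
# Classical paired tests

EXACT_WILCOXON_MAX_N = 12


def wilcoxon_signed_rank(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties get mid-ranks.  For n <= 12 the
    two-sided p is computed by exact enumeration of the 2**n sign
    assignments conditional on the observed ranks; above that a normal
    approximation with tie correction is used.  Returns
    ``(statistic, p, method)`` where the statistic is W+ for the exact
    branch and Z for the approximate one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 3:
        raise ValueError("need at least 3 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_WILCOXON_MAX_N:
        # distribution of W+ over all sign assignments of the observed ranks
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        dev = abs(w_plus - mu)
        p = float(np.mean(np.abs(totals - mu) >= dev - 1e-12))
        return (w_plus, p, "exact")
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return (z, min(p, 1.0), "normal")


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean difference over its sample SD (n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    return float(d.mean() / sd)


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across conditions (columns) within subjects (rows).

    chi2_F = 12 / (n k (k+1)) * sum_j R_j**2 - 3 n (k+1), with mid-ranks
    for ties; p from the chi-square distribution with k-1 df.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    n, k = values.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    rsum = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rsum**2).sum()) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return (chi2, p)


# ---------------------------------------------------------------------------
# Voxel-wise permutation inference


def _stack(maps, domain_mask: BinaryMask | None):
    grid = _grid(maps[0])
    for m in maps[1:]:
        grid.require_match(_grid(m), "map")
    if domain_mask is None:
        sel = np.ones(grid.shape, dtype=bool)
    else:
        grid.require_match(domain_mask.grid, "domain mask")
        sel = domain_mask.values
    return grid, sel, np.stack([_values(m)[sel] for m in maps])


def _fwe_result(
    grid: TemplateGrid,
    sel: np.ndarray,
    t_obs: np.ndarray,
    null_max: np.ndarray,
    alpha: float,
    n_perm: int,
    rng_seed: int,
    one_sided: bool = False,
) -> VoxelwiseTestResult:
    stat = t_obs if one_sided else np.abs(t_obs)
    sorted_null = np.sort(null_max)
    pvals = (n_perm - np.searchsorted(sorted_null, stat, side="left")) / n_perm
    big = np.abs(t_obs) >= T_SENTINEL
    pvals[big & (stat > 0)] = 1.0 / n_perm
    pvals[big & (stat <= 0)] = 1.0
    t_vol = np.zeros(grid.shape)
    t_vol[sel] = t_obs
    p_vol = np.ones(grid.shape)
    p_vol[sel] = pvals
    sig = np.zeros(grid.shape, dtype=bool)
    sig[sel] = pvals <= alpha
    return VoxelwiseTestResult(
        Volume3D(grid, t_vol),
        Volume3D(grid, p_vol),
        BinaryMask(grid, sig),
        alpha,
        n_perm,
        rng_seed,
    )


def _one_sample_t(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    mu = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    flat = sd == 0
    t = np.where(flat, 0.0, mu / np.where(flat, 1.0, sd / math.sqrt(n)))
    t[flat & (mu != 0)] = np.sign(mu[flat & (mu != 0)]) * T_SENTINEL
    return t


def paired_voxelwise_test(
    maps_a: list,
    maps_b: list,
    n_perm: int = 5000,
    alpha: float = 0.025,
    rng_seed: int = 0,
    domain_mask: BinaryMask | None = None,
) -> PairedVoxelwiseResult:
    """Paired voxel-wise permutation test with one-sided max-t FWE control.

    Both contrasts (a > b and b > a) are tested, each at ``alpha`` — 0.025
    per contrast corresponds to two-tailed 0.05.  The null sign-flips the
    whole paired-difference maps; the identity flip is always included.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("paired lists must have equal length")
    if len(maps_a) < 2:
        raise ValueError("need at least 2 pairs")
    grid, sel, A = _stack(maps_a, domain_mask)
    _, _, B = _stack(maps_b, domain_mask)
    D = A - B
    n = D.shape[0]
    t_obs = _one_sample_t(D)
    rng = np.random.default_rng(rng_seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for p in range(n_perm):
        signs = np.ones(n) if p == 0 else rng.choice([-1.0, 1.0], size=n)
        t_p = _one_sample_t(signs[:, None] * D)
        finite = np.abs(t_p) < T_SENTINEL
        if finite.any():
            null_pos[p] = t_p[finite].max()
            null_neg[p] = (-t_p[finite]).max()
        else:
            null_pos[p] = null_neg[p] = 0.0
    res_ab = _fwe_result(grid, sel, t_obs, null_pos, alpha, n_perm, rng_seed, one_sided=True)
    res_ba = _fwe_result(grid, sel, -t_obs, null_neg, alpha, n_perm, rng_seed, one_sided=True)
    return PairedVoxelwiseResult(res_ab, res_ba)


def _two_sample_t(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na, nb = A.shape[0], B.shape[0]
    mua, mub = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    flat = se == 0
    t = np.where(flat, 0.0, (mua - mub) / np.where(flat, 1.0, se))
    diff = mua - mub
    t[flat & (diff != 0)] = np.sign(diff[flat & (diff != 0)]) * T_SENTINEL
    return t


def two_sample_voxelwise_test(
    group_a: list,
    group_b: list,
    n_perm: int = 5000,
    alpha: float = 0.05,
    rng_seed: int = 0,
    domain_mask: BinaryMask | None = None,
) -> VoxelwiseTestResult:
    """Two-sample voxel-wise test, group-label permutation, max-|t| FWE."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 maps")
    grid, sel, A = _stack(group_a, domain_mask)
    _, _, B = _stack(group_b, domain_mask)
    na = A.shape[0]
    Y = np.vstack([A, B])
    t_obs = _two_sample_t(A, B)
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        idx = np.arange(len(Y)) if p == 0 else rng.permutation(len(Y))
        t_p = _two_sample_t(Y[idx[:na]], Y[idx[na:]])
        finite = np.abs(t_p) < T_SENTINEL
        null_max[p] = np.abs(t_p[finite]).max() if finite.any() else 0.0
    return _fwe_result(grid, sel, t_obs, null_max, alpha, n_perm, rng_seed)


def voxelwise_behaviour_correlation(
    maps: list,
    scores,
    lesion_sizes,
    n_perm: int = 5000,
    alpha: float = 0.01,
    rng_seed: int = 0,
    domain_mask: BinaryMask | None = None,
) -> VoxelwiseTestResult:
    """Voxel-wise correlation of map values with behaviour, lesion size as
    nuisance covariate, Freedman-Lane permutation, max-|t| FWE.

    Map values at each voxel are regressed on the score with an intercept
    and the lesion volume as nuisance; the null is built by permuting the
    reduced-model residuals of the data (Freedman-Lane, the scheme used by
    permutation tools for covariate designs).
    """
    scores = np.asarray(scores, dtype=float)
    lesion_sizes = np.asarray(lesion_sizes, dtype=float)
    n = len(maps)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if scores.shape != (n,) or lesion_sizes.shape != (n,):
        raise ValueError("one score and one lesion size per map required")
    if scores.std() == 0:
        raise ValueError("constant scores")
    grid, sel, Y = _stack(maps, domain_mask)
    Z = np.column_stack([np.ones(n), lesion_sizes])
    Hz = Z @ np.linalg.pinv(Z)
    s_r = scores - Hz @ scores
    if np.allclose(s_r, 0):
        raise ValueError("score is collinear with the lesion-size covariate")
    s_r = s_r / np.linalg.norm(s_r)
    E = Y - Hz @ Y  # reduced-model residuals per voxel
    df = n - 3  # intercept + size + score

    def tstat(resid: np.ndarray) -> np.ndarray:
        resid = resid - Hz @ resid
        norms = np.linalg.norm(resid, axis=0)
        flat = norms == 0
        r = (s_r @ resid) / np.where(flat, 1.0, norms)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df) / np.sqrt(np.maximum(1.0 - r**2, 0.0))
        t[np.abs(r) == 1.0] = np.sign(r[np.abs(r) == 1.0]) * T_SENTINEL
        t[flat] = 0.0
        return t

    t_obs = tstat(E)
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        idx = np.arange(n) if p == 0 else rng.permutation(n)
        t_p = tstat(E[idx])
        finite = np.abs(t_p) < T_SENTINEL
        null_max[p] = np.abs(t_p[finite]).max() if finite.any() else 0.0
    return _fwe_result(grid, sel, t_obs, null_max, alpha, n_perm, rng_seed)
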