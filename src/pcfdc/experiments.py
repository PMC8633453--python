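"""Replicate-level validation experiments on the synthetic study conditions.

These procedures exercise the package end to end under the generator's
default conditions and summarize the outcome across seeded replicates:
oracle agreement for the PCA and ridge cores, tissue selectivity of the
refined seeds, the FDC/PC-FDC connectivity-strength crossover, winner-take-
all network assignment, behaviour-prediction recovery and its type-I error
behaviour.  Problem sizes are chosen so the whole battery runs on one CPU
in minutes; docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .mapping import lesion_network_map, one_sample_tmap, NetworkMap
from .mapstats import CanonicalAtlas, map_mean_sd, nci
from .prediction import (
    default_lambda_grid,
    loocv_predict,
    pca_reduce_maps,
    permutation_significance,
    ridge_weights,
    znormalize_features,
)
from .seed import (
    build_strength_matrix,
    exclude_outlier_subjects,
    fdc_seed,
    pc1_coefficients,
    pcfdc_seed,
    threshold_seed,
)
from .synthetic import atlas_from_networks, default_study, make_lesion
from .volumes import TemplateGrid, Volume3D, mask_voxel_indices

__all__ = [
    "pc1_oracle",
    "loocv_oracle",
    "tissue_selectivity",
    "strength_crossover",
    "network_assignment",
    "behaviour_recovery",
    "null_behaviour_uniformity",
    "fwe_null_rate",
]


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_pc1(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reference PC1 via eigendecomposition of the voxel covariance matrix.

    Deliberately a different route from the SVD used by
    ``pc1_coefficients``: centre subjects x voxels, form the n x n
    covariance, take the top eigenvector.
    """
    X = values.T  # (m, n)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evecs[:, order[0]], evals / evals.sum()


def pc1_oracle(n_matrices: int = 50, rng_seed: int = 0) -> dict:
    """Max deviation of pc1_coefficients from the eigendecomposition oracle."""
    from .seed import StrengthMatrix

    rng = np.random.default_rng(rng_seed)
    worst_coef = 0.0
    worst_evr = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(2, 21))
        m = int(rng.integers(3, 11))
        vals = rng.normal(size=(n, m))
        sm = StrengthMatrix(
            np.column_stack([np.arange(n)] * 3), [f"s{j}" for j in range(m)], vals
        )
        res = pc1_coefficients(sm)
        ref_vec, ref_evr = brute_force_pc1(vals)
        if np.dot(ref_vec, res.coefficients) < 0:
            ref_vec = -ref_vec
        worst_coef = max(worst_coef, float(np.abs(ref_vec - res.coefficients).max()))
        k = min(len(ref_evr), len(res.explained_variance_ratio))
        worst_evr = max(
            worst_evr,
            float(np.abs(ref_evr[:k] - res.explained_variance_ratio[:k]).max()),
        )
    return {"max_coef_diff": worst_coef, "max_evr_diff": worst_evr, "n": n_matrices}


def brute_force_loocv(X: np.ndarray, Y: np.ndarray, grid: np.ndarray):
    """Reference nested LOOCV that refits every inner fold explicitly."""
    n = X.shape[0]
    preds = np.empty(n)
    lambdas = np.empty(n)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xt, Yt = X[tr], Y[tr]
        best = (np.inf, None)
        for lam in grid:
            err = 0.0
            for j in range(len(tr)):
                inner = np.delete(np.arange(len(tr)), j)
                w = ridge_weights(Xt[inner], Yt[inner], lam)
                err += (Yt[j] - Xt[j] @ w) ** 2
            if err < best[0] - 0.0:  # strict: ties keep the earlier (smaller) lambda
                best = (err, lam)
        lam = best[1]
        w = ridge_weights(Xt, Yt, lam)
        preds[i] = X[i] @ w
        lambdas[i] = lam
    return preds, lambdas


def loocv_oracle(
    n_subjects: int = 20, n_features: int = 5, n_grid: int = 25, rng_seed: int = 0
) -> dict:
    """Agreement of the SVD-shortcut nested LOOCV with brute-force refits."""
    rng = np.random.default_rng(rng_seed)
    X = rng.normal(size=(n_subjects, n_features))
    w_true = rng.normal(size=n_features)
    Y = X @ w_true + rng.normal(scale=0.5, size=n_subjects)
    grid = default_lambda_grid(n_grid)
    res = loocv_predict(X, Y, grid=grid)
    ref_pred, ref_lam = brute_force_loocv(X, Y, grid)
    return {
        "max_pred_diff": float(np.abs(res.predictions - ref_pred).max()),
        "max_lambda_ratio_err": float(
            np.abs(np.log(res.per_fold_lambda / ref_lam)).max()
        ),
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# Mechanism experiments on the synthetic study conditions


def _replicate_cohort(rep: int, base_seed: int, **kwargs):
    cohort = default_study(base_seed + 17 * rep, **kwargs)
    net = cohort.atlas[rep % len(cohort.atlas)]
    lesion = make_lesion(
        cohort.grid, cohort.tissue, net,
        n_gm_voxels=10, n_wm_voxels=10, rng_seed=base_seed + 17 * rep + 1,
    )
    return cohort, net, lesion


def tissue_selectivity(n_replicates: int = 50, rng_seed: int = 0) -> dict:
    """Do coherent (network GM) lesion voxels dominate the PC1 coefficients?

    Lesions are half network-GM ("coherent") and half white matter.  Reports
    the fraction of replicates where the mean |PC1 coefficient| of coherent
    voxels exceeds that of the remaining voxels, and the pooled fraction of
    coherent voxels among those retained at the 50th percentile.
    """
    wins = 0
    kept = 0
    kept_coherent = 0
    for rep in range(n_replicates):
        cohort, net, lesion = _replicate_cohort(rep, rng_seed + 1000)
        sm = exclude_outlier_subjects(build_strength_matrix(cohort.runs, lesion))
        p1 = pc1_coefficients(sm)
        member = net.spatial_map.values
        coherent = np.array([member[tuple(v)] for v in p1.voxel_order])
        a = np.abs(p1.coefficients)
        if a[coherent].mean() > a[~coherent].mean():
            wins += 1
        seed50 = threshold_seed(p1, lesion, percentile=50)
        for v in mask_voxel_indices(seed50.mask):
            kept += 1
            kept_coherent += bool(member[tuple(v)])
    return {
        "win_rate": wins / n_replicates,
        "seed_purity_p50": kept_coherent / kept,
        "n": n_replicates,
    }


def strength_crossover(n_replicates: int = 20, rng_seed: int = 0) -> dict:
    """FDC vs PC-FDC connectivity strength at low and high thresholds.

    The whole-lesion seed inherits the diffuse white-matter coherence and
    should win on the global positive mean; the refined seed concentrates
    on the lesioned network and should win above z > 0.2.
    """
    fdc_global = 0
    pcfdc_high = 0
    for rep in range(n_replicates):
        cohort, net, lesion = _replicate_cohort(rep, rng_seed + 2000)
        brain = cohort.tissue.brain_mask
        seed, _ = pcfdc_seed(cohort.runs, lesion)
        rm_pc = lesion_network_map(cohort.runs, seed)
        rm_fdc = lesion_network_map(cohort.runs, fdc_seed(lesion))
        if map_mean_sd(rm_fdc, 0.0, brain)[0] > map_mean_sd(rm_pc, 0.0, brain)[0]:
            fdc_global += 1
        if map_mean_sd(rm_pc, 0.2, brain)[0] > map_mean_sd(rm_fdc, 0.2, brain)[0]:
            pcfdc_high += 1
    return {
        "fdc_global_win_rate": fdc_global / n_replicates,
        "pcfdc_thresholded_win_rate": pcfdc_high / n_replicates,
        "n": n_replicates,
    }


def network_assignment(n_replicates: int = 30, rng_seed: int = 0) -> dict:
    """How often is the lesioned planted network the NCI winner?"""
    hits = 0
    for rep in range(n_replicates):
        cohort, net, lesion = _replicate_cohort(rep, rng_seed + 3000)
        seed, _ = pcfdc_seed(cohort.runs, lesion)
        rmap = lesion_network_map(cohort.runs, seed)
        atlas = CanonicalAtlas(atlas_from_networks(cohort.atlas))
        res = nci(rmap, atlas, cohort.tissue.brain_mask)
        hits += res.winner == net.name
    return {"winner_rate": hits / n_replicates, "n": n_replicates}


# ---------------------------------------------------------------------------
# Behaviour prediction experiments


def _synthetic_map_set(
    n_subjects: int,
    rng: np.random.Generator,
    grid_shape=(10, 10, 10),
    n_patterns: int = 4,
    map_noise_sd: float = 1.0,
):
    """Subject maps spanning a few spatial patterns plus voxel noise."""
    grid = TemplateGrid.isotropic(grid_shape)
    v = int(np.prod(grid_shape))
    patterns = rng.normal(size=(n_patterns, v))
    loadings = rng.normal(size=(n_subjects, n_patterns))
    flat = loadings @ patterns + rng.normal(scale=map_noise_sd, size=(n_subjects, v))
    maps = [NetworkMap(grid, flat[i].reshape(grid_shape), "rmap") for i in range(n_subjects)]
    weight = Volume3D(grid, (patterns[0] / v).reshape(grid_shape))
    return maps, weight


def behaviour_recovery(
    n_replicates: int = 20,
    n_subjects: int = 60,
    n_perm: int = 500,
    snr: float = 2.0,
    rng_seed: int = 0,
) -> dict:
    """Recovery of a linear behaviour signal: R2 > 0 and permutation p < 0.05.

    Behaviour is a linear functional of the subject maps plus Gaussian noise
    whose SD is the signal SD divided by ``snr``.
    """
    successes = 0
    r2s = []
    ps = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(rng_seed + 4000 + 31 * rep)
        maps, weight = _synthetic_map_set(n_subjects, rng)
        signal = np.array([float(weight.values.ravel() @ m.values.ravel()) for m in maps])
        y = signal + rng.normal(scale=signal.std() / snr, size=n_subjects)
        fm = znormalize_features(pca_reduce_maps(maps))
        yz = (y - y.mean()) / y.std()
        res = loocv_predict(fm.scores, yz)
        perm = permutation_significance(
            fm.scores, yz, n_perm=n_perm, rng_seed=rng_seed + 5000 + rep
        )
        r2s.append(res.r2)
        ps.append(perm.p)
        successes += (res.r2 > 0) and (perm.p < 0.05)
    return {
        "success_rate": successes / n_replicates,
        "median_r2": float(np.median(r2s)),
        "median_p": float(np.median(ps)),
        "n": n_replicates,
    }


def null_behaviour_uniformity(
    n_replicates: int = 50,
    n_subjects: int = 20,
    n_perm: int = 200,
    rng_seed: int = 0,
) -> dict:
    """Permutation p-values under null behaviour should be uniform."""
    pvals = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(rng_seed + 6000 + 13 * rep)
        maps, _ = _synthetic_map_set(n_subjects, rng, grid_shape=(6, 6, 6), n_patterns=3)
        y = rng.normal(size=n_subjects)
        fm = znormalize_features(pca_reduce_maps(maps))
        yz = (y - y.mean()) / y.std()
        perm = permutation_significance(
            fm.scores, yz, n_perm=n_perm, rng_seed=rng_seed + 7000 + rep
        )
        pvals.append(perm.p)
    ks = sps.kstest(pvals, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "fraction_below_05": float(np.mean(np.array(pvals) < 0.05)),
        "n": n_replicates,
    }


def fwe_null_rate(
    n_replicates: int = 100,
    n_subjects: int = 10,
    n_perm: int = 200,
    alpha: float = 0.05,
    grid_shape=(8, 8, 8),
    rng_seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of the one-sample t-map under the null."""
    grid = TemplateGrid.isotropic(grid_shape)
    rng = np.random.default_rng(rng_seed + 8000)
    families_with_fp = 0
    for rep in range(n_replicates):
        maps = [
            NetworkMap(grid, rng.normal(size=grid_shape), "rmap")
            for _ in range(n_subjects)
        ]
        _, pmap = one_sample_tmap(maps, n_perm=n_perm, rng_seed=rng_seed + 9000 + rep)
        families_with_fp += bool((pmap.values <= alpha).any())
    return {"fwe_rate": families_with_fp / n_replicates, "n": n_replicates}
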