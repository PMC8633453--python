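"""Whole-brain lesion network maps from a seed region.

A seed's mean time-course is correlated with every brain voxel in each
normative subject, Fisher z-transformed (single-subject map), and the
per-subject maps are averaged into the lesion's r-map.  A one-sample
permutation t-map with max-statistic family-wise error control is
available on top of the per-subject maps; the sign-flipping null is exact
for the symmetric one-sample hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seed import SeedMask, fisher_z
from .volumes import BinaryMask, BoldRun, TemplateGrid, Volume3D

__all__ = [
    "NetworkMap",
    "mean_seed_timecourse",
    "seed_correlation_map",
    "average_rmap",
    "one_sample_tmap",
    "lesion_network_map",
]

T_SENTINEL = 1e10  # stands in for infinite t at zero-variance voxels


@dataclass
class NetworkMap:
    """A 3D map of Fisher-z values (r-map) or t statistics (t-map)."""

    grid: TemplateGrid
    values: np.ndarray
    kind: str  # "rmap" or "tmap"
    seed: SeedMask | None = None
    n_subjects_used: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("rmap", "tmap"):
            raise ValueError("kind must be 'rmap' or 'tmap'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("map shape does not match grid")

    def as_volume(self) -> Volume3D:
        return Volume3D(self.grid, self.values)


def mean_seed_timecourse(run: BoldRun, seed: SeedMask) -> np.ndarray:
    """Arithmetic mean of the seed voxels' series at each timepoint."""
    run.grid.require_match(seed.mask.grid, "seed")
    usable = seed.mask.values & run.brain_mask.values
    if not usable.any():
        raise ValueError("seed has no voxels inside the brain mask")
    return run.series[usable].mean(axis=0)


def seed_correlation_map(run: BoldRun, seed: SeedMask) -> NetworkMap:
    """Single-subject Fisher-z correlation map of the seed's mean time-course.

    Voxels outside the brain mask are set to 0; zero-variance voxels inside
    the mask get z = 0 with a warning (their correlation is undefined).
    """
    tc = mean_seed_timecourse(run, seed)
    tc_c = tc - tc.mean()
    tc_sd = tc_c.std()
    if tc_sd == 0:
        raise ValueError("seed mean time-course has zero variance")
    brain = run.brain_mask.values
    X = run.series[brain]
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance voxels set to z=0", RuntimeWarning
        )
    denom = np.where(flat, 1.0, sd * tc_sd * len(tc))
    r = (Xc @ tc_c) / denom
    r[flat] = 0.0
    z = fisher_z(r)
    out = np.zeros(run.grid.shape)
    out[brain] = z
    return NetworkMap(run.grid, out, "rmap", seed=seed, n_subjects_used=1)


def average_rmap(maps: list[NetworkMap]) -> NetworkMap:
    """Voxel-wise mean of single-subject z-maps: the lesion's r-map."""
    if not maps:
        raise ValueError("no maps to average")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid, "map")
        if maps[0].seed is not None and m.seed is not None:
            if not np.array_equal(maps[0].seed.mask.values, m.seed.mask.values):
                raise ValueError("maps were computed from different seeds")
    mean = np.mean([m.values for m in maps], axis=0)
    return NetworkMap(
        grid, mean, "rmap", seed=maps[0].seed, n_subjects_used=len(maps)
    )


def one_sample_tmap(
    maps: list[NetworkMap],
    n_perm: int = 5000,
    rng_seed: int = 0,
    brain_mask: BinaryMask | None = None,
) -> tuple[NetworkMap, Volume3D]:
    """One-sample t-map over subject maps with sign-flip max-|t| FWE p-values.

    The null hypothesis is symmetric subject maps around zero; whole maps
    are sign-flipped.  The identity flip is always part of the null set, so
    p-values are never below 1/n_perm.  Voxels with zero between-subject
    variance get t = 0 when their mean is 0, otherwise a signed sentinel
    excluded from the max-statistic null.
    """
    if len(maps) < 2:
        raise ValueError("t-map needs at least 2 subject maps")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = maps[0].grid
    for m in maps[1:]:
        grid.require_match(m.grid, "map")
    if brain_mask is None:
        sel = np.ones(grid.shape, dtype=bool)
    else:
        grid.require_match(brain_mask.grid, "brain mask")
        sel = brain_mask.values
    Y = np.stack([m.values[sel] for m in maps])  # (n, v)
    n = Y.shape[0]

    def tstat(data: np.ndarray) -> np.ndarray:
        mu = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        flat = sd == 0
        t = np.where(flat, 0.0, mu / np.where(flat, 1.0, sd / np.sqrt(n)))
        t[flat & (mu != 0)] = np.sign(mu[flat & (mu != 0)]) * T_SENTINEL
        return t

    t_obs = tstat(Y)
    valid = np.abs(t_obs) < T_SENTINEL
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        if p == 0:
            signs = np.ones(n)
        else:
            signs = rng.choice([-1.0, 1.0], size=n)
        t_p = tstat(signs[:, None] * Y)
        finite = np.abs(t_p) < T_SENTINEL
        null_max[p] = np.abs(t_p[finite]).max() if finite.any() else 0.0
    sorted_null = np.sort(null_max)
    pvals = (n_perm - np.searchsorted(sorted_null, np.abs(t_obs), side="left")) / n_perm
    # sentinel voxels beat every finite null maximum
    pvals[~valid & (t_obs != 0)] = 1.0 / n_perm

    t_vol = np.zeros(grid.shape)
    t_vol[sel] = t_obs
    p_vol = np.ones(grid.shape)
    p_vol[sel] = pvals
    tmap = NetworkMap(
        grid, t_vol, "tmap", seed=maps[0].seed, n_subjects_used=len(maps)
    )
    return tmap, Volume3D(grid, p_vol)


def lesion_network_map(runs: list[BoldRun], seed: SeedMask) -> NetworkMap:
    """Convenience: per-subject seed correlation maps averaged into an r-map."""
    return average_rmap([seed_correlation_map(run, seed) for run in runs])
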