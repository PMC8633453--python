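"""PCA-refined lesion seeds (PC-FDC) and the whole-lesion baseline (FDC).

The refinement works on the *within-lesion connectivity strength* matrix.
For one normative subject, the n lesion voxels' time-series give an n x n
Pearson correlation matrix; correlations are Fisher z-transformed and each
row averaged (excluding the diagonal) into a length-n strength vector —
each voxel's mean connectivity to the rest of the lesion.  Stacking these
vectors over the m normative subjects yields an n x m strength matrix.
PCA on that matrix (subjects as observations, voxels as variables,
covariance PCA) gives one first-component coefficient per lesion voxel.
Voxels whose time-series cohere across the lesion — predominantly grey
matter — share the dominant axis and receive large |PC1| coefficients;
thresholding |coefficients| at a percentile (default 20th, strictly
greater) yields the refined seed mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import BinaryMask, BoldRun, mask_from_indices, mask_voxel_indices

__all__ = [
    "LesionTimeseries",
    "StrengthMatrix",
    "Pc1Result",
    "SeedMask",
    "extract_lesion_timeseries",
    "within_lesion_strength",
    "build_strength_matrix",
    "exclude_outlier_subjects",
    "pc1_coefficients",
    "threshold_seed",
    "fdc_seed",
    "pcfdc_seed",
]

R_CLIP = 1.0 - 1e-7  # |r| clipped here before atanh so duplicates stay finite


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to 1 - 1e-7; warns when clipping occurs."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > R_CLIP):
        warnings.warn(
            "correlations with |r| ~ 1 clipped before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


@dataclass
class LesionTimeseries:
    """Lesion-voxel time-series, rows in canonical voxel order."""

    voxel_order: np.ndarray  # (n, 3)
    series: np.ndarray  # (n, T)
    dropped_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))

    @property
    def n_voxels(self) -> int:
        return int(self.series.shape[0])


@dataclass
class StrengthMatrix:
    """Fisher-z mean within-lesion connectivity, one column per subject."""

    voxel_order: np.ndarray  # (n, 3)
    subjects: list[str]
    values: np.ndarray  # (n, m)
    dropped_voxels: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.voxel_order), len(self.subjects)):
            raise ValueError("strength matrix shape does not match voxel/subject lists")
        if not np.isfinite(self.values).all():
            raise ValueError("strength matrix contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[1])


@dataclass
class Pc1Result:
    """PC coefficients per lesion voxel, back-projectable to the mask."""

    voxel_order: np.ndarray
    coefficients: np.ndarray  # (n,), PC1 loading per voxel
    explained_variance_ratio: np.ndarray
    excluded_subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if evr.sum() > 1 + 1e-9 or np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing, sum <= 1")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("non-finite PC coefficients")


@dataclass
class SeedMask:
    """A seed region with provenance back to its parent lesion."""

    mask: BinaryMask
    parent_lesion: BinaryMask
    percentile_used: float | None = None

    def __post_init__(self) -> None:
        if self.mask.n_voxels == 0:
            raise ValueError("seed mask is empty")
        if (self.mask.values & ~self.parent_lesion.values).any():
            raise ValueError("seed mask must be a subset of its parent lesion")


# ---------------------------------------------------------------------------


def extract_lesion_timeseries(run: BoldRun, lesion: BinaryMask) -> LesionTimeseries:
    """Time-series of lesion voxels that are inside the brain and non-flat.

    Voxels outside the run's brain mask and voxels with zero temporal
    variance are dropped and reported in ``dropped_voxels``.
    """
    run.grid.require_match(lesion.grid, "lesion")
    all_voxels = mask_voxel_indices(lesion)
    in_brain = run.brain_mask.values[all_voxels[:, 0], all_voxels[:, 1], all_voxels[:, 2]]
    if not in_brain.any():
        raise ValueError(
            "lesion has no voxels inside the brain mask (misaligned lesion?)"
        )
    order = all_voxels[in_brain]
    series = run.series[order[:, 0], order[:, 1], order[:, 2]]
    flat = series.std(axis=1) == 0
    dropped = np.vstack([all_voxels[~in_brain], order[flat]]).astype(int)
    return LesionTimeseries(order[~flat], series[~flat], dropped_voxels=dropped)


def within_lesion_strength(ts: LesionTimeseries) -> np.ndarray:
    """Mean Fisher-z connectivity of each lesion voxel to the rest of the lesion.

    Row averages exclude the diagonal: a voxel's unit self-correlation is
    not part of its strength.
    """
    n = ts.n_voxels
    if n < 2:
        raise ValueError("within-lesion strength needs at least 2 voxels")
    r = np.corrcoef(ts.series)
    np.fill_diagonal(r, 0.0)  # self-correlations are excluded from the average
    z = fisher_z(r)
    return z.sum(axis=1) / (n - 1)


def build_strength_matrix(runs: list[BoldRun], lesion: BinaryMask) -> StrengthMatrix:
    """Stack per-subject strength vectors into the n x m matrix fed to PCA.

    Voxel validity is harmonized by intersection: a voxel dropped for any
    subject (outside brain, flat series) is dropped for all, keeping the
    matrix rectangular under one voxel ordering.
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 normative subjects")
    grid = runs[0].grid
    per_subject = []
    for run in runs:
        grid.require_match(run.grid, f"run {run.subject}")
        per_subject.append(extract_lesion_timeseries(run, lesion))
    # intersection of surviving voxels across subjects
    keys = [set(map(tuple, ts.voxel_order)) for ts in per_subject]
    common = set.intersection(*keys)
    all_voxels = mask_voxel_indices(lesion)
    keep = np.array([tuple(v) in common for v in all_voxels])
    order = all_voxels[keep]
    dropped = all_voxels[~keep]
    if len(order) < 2:
        raise ValueError("fewer than 2 lesion voxels survive across all subjects")
    cols = []
    for ts in per_subject:
        lookup = {tuple(v): i for i, v in enumerate(ts.voxel_order)}
        rows = np.array([lookup[tuple(v)] for v in order])
        sub = LesionTimeseries(order, ts.series[rows])
        cols.append(within_lesion_strength(sub))
    return StrengthMatrix(
        order,
        [run.subject for run in runs],
        np.column_stack(cols),
        dropped_voxels=dropped,
    )


def exclude_outlier_subjects(sm: StrengthMatrix, k_sd: float = 3.0) -> StrengthMatrix:
    """Drop subjects whose global |strength| deviates > k_sd SDs from the mean.

    Guards the PCA against single aberrant normative brains.  With zero
    sample SD (identical columns) nothing is excluded.
    """
    if sm.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if math.isinf(k_sd):
        return sm
    g = np.abs(sm.values).mean(axis=0)
    sd = g.std(ddof=1)
    if sd == 0:
        return sm
    keep = np.abs(g - g.mean()) <= k_sd * sd
    if keep.sum() < 3:
        raise ValueError("outlier exclusion would leave fewer than 3 subjects")
    if keep.all():
        return sm
    out = StrengthMatrix(
        sm.voxel_order,
        [s for s, k in zip(sm.subjects, keep) if k],
        sm.values[:, keep],
        dropped_voxels=sm.dropped_voxels,
    )
    out.excluded = [s for s, k in zip(sm.subjects, keep) if not k]  # type: ignore[attr-defined]
    return out


def pc1_coefficients(sm: StrengthMatrix, component: int = 0) -> Pc1Result:
    """PCA of the strength matrix; one coefficient per lesion voxel.

    Subjects are observations and voxels variables; variables are centred
    across subjects, not scaled (covariance PCA), so amplitude differences
    between coherent and incoherent voxels are preserved.  The component's
    sign is fixed so its coefficients correlate non-negatively with the
    subject-mean strength vector.
    """
    if sm.n_voxels < 2 or sm.n_subjects < 3:
        raise ValueError("PCA needs >= 2 voxels and >= 3 subjects")
    X = sm.values.T  # (m subjects, n voxels)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("strength matrix has rank 0 after centring")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    evr = var / var.sum()
    if component >= len(s):
        raise ValueError(f"component {component} not available (rank {len(s)})")
    coef = Vt[component]
    mean_strength = sm.values.mean(axis=1)
    ref = mean_strength - mean_strength.mean()
    orient = float(coef @ ref)
    if orient < 0 or (orient == 0 and coef[np.nonzero(coef)[0][0]] < 0):
        coef = -coef
    excluded = getattr(sm, "excluded", [])
    return Pc1Result(sm.voxel_order, coef, evr, excluded_subjects=list(excluded))


def threshold_seed(
    pc1: Pc1Result,
    lesion: BinaryMask,
    percentile: float = 20.0,
) -> SeedMask:
    """Binarize the back-projected coefficients at a percentile cutoff.

    The cutoff is the given percentile (linear interpolation) of the
    |coefficient| distribution; voxels strictly above it are kept.  The
    default 20th percentile drops the least coherent fifth of the lesion.
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    a = np.abs(pc1.coefficients)
    cutoff = np.percentile(a, percentile)
    keep = a > cutoff
    if not keep.any():
        raise ValueError(
            "thresholding kept no voxels (all coefficients tied at the cutoff)"
        )
    mask = mask_from_indices(lesion.grid, pc1.voxel_order[keep])
    return SeedMask(mask, lesion, percentile_used=percentile)


def fdc_seed(lesion: BinaryMask) -> SeedMask:
    """The baseline seed: the entire lesion, unrefined."""
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion")
    return SeedMask(BinaryMask(lesion.grid, lesion.values.copy()), lesion, None)


def pcfdc_seed(
    runs: list[BoldRun],
    lesion: BinaryMask,
    percentile: float = 20.0,
    k_sd: float = 3.0,
    component: int = 0,
) -> tuple[SeedMask, Pc1Result]:
    """The full refinement: strength matrix -> outlier exclusion -> PCA -> threshold."""
    sm = build_strength_matrix(runs, lesion)
    sm = exclude_outlier_subjects(sm, k_sd=k_sd)
    pc1 = pc1_coefficients(sm, component=component)
    return threshold_seed(pc1, lesion, percentile=percentile), pc1
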