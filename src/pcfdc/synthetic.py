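"""Synthetic normative cohorts with planted resting-state networks.

The generator emulates the features of real normative fMRI that the
seed-refinement method exploits, and nothing else:

* a small set of pairwise-disjoint "canonical" networks, each driven by its
  own latent time-course shared by all member voxels;
* two tissue compartments: member voxels in grey matter carry the latent at
  full amplitude, member voxels in white matter at a reduced amplitude
  (``wm_signal_scale``, default 0.35 — WM BOLD amplitude is roughly a
  quarter to a half of GM);
* a weak fluctuation shared by the whole white-matter compartment
  (``wm_common_sd``), standing in for the broad, low-amplitude coherence of
  WM BOLD (vascular/physiological and crossing-fibre signal) that makes
  whole-lesion seeds produce diffuse positive connectivity;
* independent Gaussian voxel noise with per-compartment standard deviation.

The generating model is simple enough that expected correlations are
closed-form: two GM member voxels of the same network with latent sd ``s``
and noise sd ``sigma`` have expected Pearson correlation ``s**2 / (s**2 +
sigma**2)``.  Latent series are white (no autocorrelation); only
correlation structure matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import (
    BinaryMask,
    BoldRun,
    TemplateGrid,
    Volume3D,
    mask_from_indices,
    mask_voxel_indices,
    write_bold,
    write_mask,
)

__all__ = [
    "PlantedNetwork",
    "TissueModel",
    "SyntheticCohort",
    "make_normative_cohort",
    "make_lesion",
    "make_behaviour",
    "default_study",
    "atlas_from_networks",
    "write_cohort",
]


@dataclass
class PlantedNetwork:
    """A named set of member voxels sharing one latent time-course."""

    name: str
    spatial_map: BinaryMask
    timecourse_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.timecourse_sd <= 0:
            raise ValueError("timecourse_sd must be positive")
        if self.spatial_map.n_voxels < 2:
            raise ValueError(f"network {self.name} needs at least 2 voxels")


@dataclass
class TissueModel:
    """Grey/white compartments and their noise/signal parameters."""

    gm_mask: BinaryMask
    wm_mask: BinaryMask
    gm_noise_sd: float = 1.0
    wm_noise_sd: float = 1.0
    wm_signal_scale: float = 0.35
    wm_common_sd: float = 0.3

    def __post_init__(self) -> None:
        self.gm_mask.grid.require_match(self.wm_mask.grid, "wm mask")
        if (self.gm_mask.values & self.wm_mask.values).any():
            raise ValueError("gm and wm masks must be disjoint")
        if min(self.gm_noise_sd, self.wm_noise_sd) <= 0:
            raise ValueError("noise sds must be positive")
        if not 0.0 <= self.wm_signal_scale <= 1.0:
            raise ValueError("wm_signal_scale must lie in [0, 1]")
        if self.wm_common_sd < 0:
            raise ValueError("wm_common_sd must be non-negative")

    @property
    def brain_mask(self) -> BinaryMask:
        return self.gm_mask.union(self.wm_mask)


@dataclass
class SyntheticCohort:
    runs: list[BoldRun]
    atlas: list[PlantedNetwork]
    tissue: TissueModel
    rng_seed: int

    @property
    def grid(self) -> TemplateGrid:
        return self.runs[0].grid


def make_normative_cohort(
    grid: TemplateGrid,
    networks: list[PlantedNetwork],
    tissue: TissueModel,
    n_subjects: int,
    n_timepoints: int,
    rng_seed: int,
) -> SyntheticCohort:
    """Draw a cohort of independent subjects from the planted-network model.

    For each subject and network an independent latent series is drawn;
    every member voxel receives it scaled by its compartment amplitude plus
    compartment noise.  Non-member brain voxels are noise (plus the shared
    WM fluctuation in the white compartment).  Voxels outside the brain
    mask stay zero.
    """
    if n_subjects < 1 or n_timepoints < 2:
        raise ValueError("need n_subjects >= 1 and n_timepoints >= 2")
    grid.require_match(tissue.gm_mask.grid, "tissue model")
    brain = tissue.brain_mask
    occupied = np.zeros(grid.shape, dtype=bool)
    for net in networks:
        grid.require_match(net.spatial_map.grid, f"network {net.name}")
        if (occupied & net.spatial_map.values).any():
            raise ValueError(f"network {net.name} overlaps another network")
        if (net.spatial_map.values & ~brain.values).any():
            raise ValueError(f"network {net.name} extends outside the brain mask")
        occupied |= net.spatial_map.values

    rng = np.random.default_rng(rng_seed)
    gm = tissue.gm_mask.values
    wm = tissue.wm_mask.values
    runs = []
    for s in range(n_subjects):
        series = np.zeros(grid.shape + (n_timepoints,))
        series[gm] = rng.normal(0.0, tissue.gm_noise_sd, (int(gm.sum()), n_timepoints))
        series[wm] = rng.normal(0.0, tissue.wm_noise_sd, (int(wm.sum()), n_timepoints))
        if tissue.wm_common_sd > 0:
            series[wm] += rng.normal(0.0, tissue.wm_common_sd, n_timepoints)
        for net in networks:
            latent = rng.normal(0.0, net.timecourse_sd, n_timepoints)
            members = net.spatial_map.values
            amp = np.where(gm[members], 1.0, tissue.wm_signal_scale)
            series[members] += amp[:, None] * latent[None, :]
        runs.append(BoldRun(grid, series, brain, subject=f"sub-{s:03d}"))
    return SyntheticCohort(runs, list(networks), tissue, rng_seed)


def make_lesion(
    grid: TemplateGrid,
    tissue: TissueModel,
    network: PlantedNetwork,
    n_gm_voxels: int,
    n_wm_voxels: int,
    rng_seed: int,
) -> BinaryMask:
    """A binary lesion straddling grey and white matter.

    ``n_gm_voxels`` are drawn from the target network's GM members (the
    coherent compartment) and ``n_wm_voxels`` from the whole WM mask, so a
    lesion picks up white matter belonging to any network or to none —
    as real infarcts cut through fibre systems unrelated to the cortical
    area they hit.
    """
    grid.require_match(tissue.gm_mask.grid, "tissue model")
    rng = np.random.default_rng(rng_seed)
    gm_pool = mask_voxel_indices(network.spatial_map.intersect(tissue.gm_mask))
    wm_pool = mask_voxel_indices(tissue.wm_mask)
    if n_gm_voxels > len(gm_pool):
        raise ValueError(
            f"requested {n_gm_voxels} GM voxels but network {network.name} "
            f"has only {len(gm_pool)} in GM"
        )
    if n_wm_voxels > len(wm_pool):
        raise ValueError(f"requested {n_wm_voxels} WM voxels, only {len(wm_pool)} exist")
    picks = []
    if n_gm_voxels:
        picks.append(gm_pool[rng.choice(len(gm_pool), n_gm_voxels, replace=False)])
    if n_wm_voxels:
        picks.append(wm_pool[rng.choice(len(wm_pool), n_wm_voxels, replace=False)])
    if not picks:
        raise ValueError("lesion must contain at least one voxel")
    return mask_from_indices(grid, np.concatenate(picks))


def make_behaviour(
    disconnection_maps: list,
    weight_map: Volume3D,
    noise_sd: float,
    rng_seed: int,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Behavioural scores as a noisy linear functional of disconnection maps.

    ``score_i = sum_v weight(v) * map_i(v) + N(0, noise_sd)``.  The returned
    frame carries generation metadata in ``.attrs`` (true weights, noise sd)
    so recovery can be checked downstream.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(rng_seed)
    w = weight_map.values.ravel()
    scores = []
    for m in disconnection_maps:
        weight_map.grid.require_match(m.grid, "disconnection map")
        scores.append(float(w @ m.values.ravel()))
    scores = np.asarray(scores) + rng.normal(0.0, noise_sd, len(scores))
    if subjects is None:
        subjects = [f"pat-{i:03d}" for i in range(len(scores))]
    df = pd.DataFrame({"subject": subjects, "score": scores})
    df.attrs["true_weight_map"] = weight_map
    df.attrs["noise_sd"] = noise_sd
    return df


# ---------------------------------------------------------------------------
# The standard study layout used throughout the tests and examples


def default_study(
    rng_seed: int,
    shape: tuple[int, int, int] = (16, 16, 16),
    n_networks: int = 3,
    n_subjects: int = 60,
    n_timepoints: int = 150,
    timecourse_sd: float = 1.0,
    gm_noise_sd: float = 1.0,
    wm_noise_sd: float = 1.0,
    wm_signal_scale: float = 0.35,
    wm_common_sd: float = 0.3,
) -> SyntheticCohort:
    """A compact two-slab brain with planted networks.

    Grey matter is the upper slab, white matter the lower; each network has
    a GM core (48 voxels) and a small WM extension (12 voxels) beneath it.
    With unit latent and noise sds, within-network GM pairs correlate at
    0.5 in expectation.  The default of 60 normative subjects is a
    desk-scale stand-in for a large normative cohort: the stability of the
    first principal component of within-lesion strengths — the quantity the
    seed refinement rests on — requires many more subjects than lesion
    voxels.
    """
    grid = TemplateGrid.isotropic(shape, 2.0)
    nx, ny, nz = shape
    gm = np.zeros(shape, dtype=bool)
    wm = np.zeros(shape, dtype=bool)
    zmid = nz // 2
    gm[2 : nx - 2, 2 : ny - 2, zmid + 1 : min(zmid + 6, nz - 1)] = True
    wm[2 : nx - 2, 2 : ny - 2, max(zmid - 5, 1) : zmid] = True
    tissue = TissueModel(
        BinaryMask(grid, gm),
        BinaryMask(grid, wm),
        gm_noise_sd=gm_noise_sd,
        wm_noise_sd=wm_noise_sd,
        wm_signal_scale=wm_signal_scale,
        wm_common_sd=wm_common_sd,
    )
    networks = []
    for q in range(n_networks):
        x0 = 2 + 4 * q
        if x0 + 4 > nx - 2:
            raise ValueError("grid too small for the requested number of networks")
        vals = np.zeros(shape, dtype=bool)
        vals[x0 : x0 + 4, 3:9, zmid + 1 : zmid + 3] = True  # GM core, 48 voxels
        vals[x0 : x0 + 4, 3:6, zmid - 1 : zmid] = True  # WM extension, 12 voxels
        networks.append(
            PlantedNetwork(f"net-{q}", BinaryMask(grid, vals), timecourse_sd)
        )
    return make_normative_cohort(
        grid, networks, tissue, n_subjects, n_timepoints, rng_seed
    )


def atlas_from_networks(networks: list[PlantedNetwork]) -> list[tuple[str, Volume3D]]:
    """Binary template maps for the planted networks, for NCI scoring."""
    return [
        (n.name, Volume3D(n.spatial_map.grid, n.spatial_map.values.astype(float)))
        for n in networks
    ]


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write a cohort to disk: BOLD runs, tissue masks, atlas, labels."""
    outdir = Path(outdir)
    bold_dir = outdir / "bold"
    atlas_dir = outdir / "atlas"
    bold_dir.mkdir(parents=True, exist_ok=True)
    atlas_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"bold": [], "atlas": []}
    write_mask(cohort.tissue.brain_mask, outdir / "brain_mask.nii.gz")
    write_mask(cohort.tissue.gm_mask, outdir / "gm_mask.nii.gz")
    write_mask(cohort.tissue.wm_mask, outdir / "wm_mask.nii.gz")
    for run in cohort.runs:
        p = bold_dir / f"{run.subject}.nii.gz"
        write_bold(run, p)
        manifest["bold"].append(str(p))
    labels = []
    for net in cohort.atlas:
        p = atlas_dir / f"{net.name}.nii.gz"
        write_mask(net.spatial_map, p)
        labels.append(f"{net.name}\t{net.name}")
        manifest["atlas"].append(str(p))
    (atlas_dir / "labels.txt").write_text("\n".join(labels) + "\n")
    manifest["brain_mask"] = str(outdir / "brain_mask.nii.gz")
    return manifest
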