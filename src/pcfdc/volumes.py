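"""NIfTI volume I/O on a shared template grid.

Every object in an analysis — lesion masks, normative BOLD runs, network
maps, atlas templates — must live on one template grid (same shape, same
affine).  Volumes on a different grid are rejected rather than silently
resampled; an explicit nearest-neighbour resampler is provided for binary
masks only.

Voxel indices are 0-based and the canonical voxel ordering is row-major
(C order) over the stored axis order.  This ordering defines the position
of each voxel in every lesion-indexed vector or matrix downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TemplateGrid",
    "Volume3D",
    "BinaryMask",
    "BoldRun",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_bold",
    "write_bold",
    "mask_voxel_indices",
    "mask_from_indices",
    "resample_mask_nearest",
    "read_atlas",
]

_GRID_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Two volumes do not share the template grid."""


@dataclass(frozen=True)
class TemplateGrid:
    """Shape and voxel-to-world affine shared by all volumes in an analysis."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (norms of the affine's spatial columns)."""
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "TemplateGrid", atol: float = _GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "TemplateGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} is on a different grid: shape {other.shape} vs "
                f"{self.shape} (or affine differs)"
            )

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float = 2.0) -> "TemplateGrid":
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), affine)


@dataclass
class Volume3D:
    """A scalar value per voxel on a template grid."""

    grid: TemplateGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """A {0,1} volume on a template grid."""

    grid: TemplateGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:5]}")
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {arr.shape} != grid shape {self.grid.shape}"
            )
        self.values = arr.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_match(other.grid, "mask")
        return BinaryMask(self.grid, self.values & other.values)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_match(other.grid, "mask")
        return BinaryMask(self.grid, self.values | other.values)


@dataclass
class BoldRun:
    """One normative subject's 4D BOLD series with its brain mask.

    ``series`` is stored as a 4D array (x, y, z, t).  Within the brain mask
    every voxel's time-series must be finite; outside the mask anything goes.
    """

    grid: TemplateGrid
    series: np.ndarray
    brain_mask: BinaryMask
    subject: str = "sub"

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 4:
            raise ValueError("BOLD series must be 4D (x, y, z, t)")
        if self.series.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"series spatial shape {self.series.shape[:3]} != grid {self.grid.shape}"
            )
        self.grid.require_match(self.brain_mask.grid, "brain mask")
        if self.n_timepoints < 2:
            raise ValueError("BOLD run needs at least 2 timepoints")
        inside = self.series[self.brain_mask.values]
        bad = ~np.isfinite(inside).all(axis=1)
        if bad.any():
            idx = mask_voxel_indices(self.brain_mask)[np.flatnonzero(bad)[0]]
            raise ValueError(
                "non-finite time-series inside brain mask at voxel "
                f"{tuple(int(i) for i in idx)}"
            )

    @property
    def n_timepoints(self) -> int:
        return int(self.series.shape[3])


# ---------------------------------------------------------------------------
# I/O


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_volume(path: str | Path) -> Volume3D:
    """Read a 3D NIfTI volume.  4D inputs are rejected by this entry point."""
    img = _load(path)
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} dimensions")
    grid = TemplateGrid(data.shape, img.affine)
    return Volume3D(grid, data.astype(float))


def write_volume(vol: Volume3D, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), vol.grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    vals = vol.values
    if not np.all(np.isin(np.unique(vals), (0, 1))):
        raise ValueError(f"{path}: mask file contains values other than 0/1")
    return BinaryMask(vol.grid, vals.astype(bool))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_bold(path: str | Path, brain_mask: BinaryMask, subject: str | None = None) -> BoldRun:
    """Read a 4D NIfTI run and validate it against ``brain_mask``'s grid."""
    img = _load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D run, got {data.ndim} dimensions")
    grid = TemplateGrid(data.shape[:3], img.affine)
    grid.require_match(brain_mask.grid, f"brain mask for {path}")
    if data.shape[3] < 2:
        raise ValueError(f"{path}: fewer than 2 timepoints")
    name = subject if subject is not None else Path(path).name.split(".")[0]
    return BoldRun(grid, data, brain_mask, subject=name)


def write_bold(run: BoldRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.series.astype(np.float64), run.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Mask utilities


def mask_voxel_indices(mask: BinaryMask) -> np.ndarray:
    """(n, 3) array of 0-based voxel indices in canonical row-major order.

    This ordering is the contract for every lesion-indexed vector/matrix:
    row i of a within-lesion object always refers to voxel ``indices[i]``.
    """
    return np.argwhere(mask.values)  # argwhere scans in C (row-major) order


def mask_from_indices(grid: TemplateGrid, indices: np.ndarray) -> BinaryMask:
    vals = np.zeros(grid.shape, dtype=bool)
    idx = np.asarray(indices, dtype=int)
    if idx.size:
        vals[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return BinaryMask(grid, vals)


def resample_mask_nearest(mask: BinaryMask, target: TemplateGrid) -> BinaryMask:
    """Nearest-neighbour resampling of a binary mask onto another grid.

    The only resampling this package performs; continuous volumes must be
    supplied on the template grid already.
    """
    # map target voxel centres through target affine, then inverse source affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in target.shape), indexing="ij")
    coords = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4).T
    world = target.affine @ coords
    src = np.linalg.inv(mask.grid.affine) @ world
    src = np.round(src[:3]).astype(int)
    inside = np.all((src >= 0) & (src < np.array(mask.grid.shape)[:, None]), axis=0)
    out = np.zeros(target.n_voxels, dtype=bool)
    out[inside] = mask.values[src[0, inside], src[1, inside], src[2, inside]]
    return BinaryMask(target, out.reshape(target.shape))


def read_atlas(path: str | Path) -> list[tuple[str, Volume3D]]:
    """Read a canonical-network atlas as ``[(name, template map), ...]``.

    Two layouts are accepted:

    * one labelled integer volume plus a sibling ``labels.txt`` with one
      ``index<TAB>name`` per line — each label becomes a binary template;
    * a directory of per-network 3D maps plus ``labels.txt`` mapping file
      stems to names (``stem<TAB>name``); absent a label file, file stems
      are used as names.
    """
    path = Path(path)
    if path.is_dir():
        labels: dict[str, str] = {}
        label_file = path / "labels.txt"
        if label_file.exists():
            for line in label_file.read_text().splitlines():
                if line.strip():
                    key, name = line.split("\t")
                    labels[key] = name
        out = []
        for f in sorted(path.glob("*.nii*")):
            stem = f.name.split(".")[0]
            out.append((labels.get(stem, stem), read_volume(f)))
        if not out:
            raise FileNotFoundError(f"no NIfTI maps found in atlas directory {path}")
        return out
    vol = read_volume(path)
    label_file = path.parent / "labels.txt"
    if not label_file.exists():
        raise FileNotFoundError(
            f"labelled atlas volume {path} needs a sibling labels.txt"
        )
    out = []
    for line in label_file.read_text().splitlines():
        if not line.strip():
            continue
        idx, name = line.split("\t")
        out.append((name, Volume3D(vol.grid, (vol.values == int(idx)).astype(float))))
    return out
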