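"""Volume containers, NIfTI/TIFF I/O and threshold-based myocardial segmentation.

The segmentation here is a deliberately simple, fully deterministic
stand-in for interactive semiautomatic tools: intensity threshold,
one-voxel morphological cleanup, and largest-component selection.

Voxel coordinate convention (shared with :mod:`lvatlas.meshfit`):
0-based indices; the centre of voxel ``i`` lies at
``origin + (i + 0.5) * spacing``; extents are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "Volume",
    "MaskVolume",
    "SegmentationError",
    "segment_myocardium",
    "save_volume",
    "load_volume",
]


class SegmentationError(RuntimeError):
    """Raised when segmentation cannot produce a valid myocardial mask."""


@dataclass
class Volume:
    """A 3D image with voxel spacing and world origin (mm).

    ``voxels`` is indexed ``[x, y, z]``; the centre of voxel ``(i, j, k)``
    is at ``origin_mm + (index + 0.5) * spacing_mm``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def voxel_centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-centre world coordinates."""
        idx = np.indices(self.voxels.shape).reshape(3, -1).T
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.spacing_mm)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (mm)."""
        pts = np.atleast_2d(points_mm)
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm) - 0.5


@dataclass
class MaskVolume(Volume):
    """Binary myocardial mask; foreground is the myocardium shell."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.voxels = self.voxels.astype(bool)

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def foreground_centers(self) -> np.ndarray:
        idx = np.argwhere(self.voxels)
        return np.asarray(self.origin_mm) + (idx + 0.5) * np.asarray(self.spacing_mm)


# six-connected structuring element, shared by cleanup and labelling
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _largest_component(mask: np.ndarray, min_component_voxels: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT6)
    if n == 0:
        raise SegmentationError("segmentation produced an empty mask")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_voxels) + 1
    if keep.size == 0:
        raise SegmentationError(
            f"all components smaller than min_component_voxels={min_component_voxels}"
        )
    best = sizes[keep - 1].max()
    candidates = keep[sizes[keep - 1] == best]
    if candidates.size > 1:
        # deterministic tie-break: smallest lexicographic minimal voxel index
        firsts = []
        for lab in candidates:
            firsts.append(tuple(np.argwhere(labels == lab)[0]))
        candidates = [c for _, c in sorted(zip(firsts, candidates))]
    return labels == candidates[0]


def segment_myocardium(
    volume: Volume,
    percentile: float | None = None,
    min_component_voxels: int = 27,
) -> MaskVolume:
    """Threshold-and-cleanup segmentation of the myocardium.

    Parameters
    ----------
    volume:
        Grayscale image volume.
    percentile:
        Intensity percentile (0–100) used as the threshold.  ``None``
        selects the threshold automatically by Otsu's method, which is
        robust to the myocardium occupying different volume fractions.
    min_component_voxels:
        Connected components (6-connectivity) smaller than this are
        discarded before the largest component is retained.

    Returns
    -------
    MaskVolume
        Single 6-connected foreground component after a one-voxel binary
        closing + opening.

    Raises
    ------
    SegmentationError
        If the volume is constant or nothing survives the cleanup.
    """
    gray = np.asarray(volume.voxels, dtype=float)
    if np.ptp(gray) == 0:
        raise SegmentationError("constant-intensity volume cannot be segmented")
    if percentile is None:
        thr = threshold_otsu(gray)
    else:
        if not 0 < percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        thr = np.percentile(gray, percentile)
    binary = gray > thr
    # one-voxel cleanup by morphological reconstruction: the closing fills
    # pinholes and the opening removes speckle spurs, while structures that
    # survive the erosion are restored voxel-exactly (a plain opening would
    # also shave single-voxel ridges off curved surfaces).
    holes = ~binary
    hole_seed = ndimage.binary_erosion(holes, structure=_STRUCT6, border_value=1)
    binary = ~ndimage.binary_propagation(hole_seed, structure=_STRUCT6, mask=holes)
    seed = ndimage.binary_erosion(binary, structure=_STRUCT6)
    binary = ndimage.binary_propagation(seed, structure=_STRUCT6, mask=binary)
    binary = _largest_component(binary, min_component_voxels)
    return MaskVolume(binary, volume.spacing_mm, volume.origin_mm)


# ---------------------------------------------------------------------------
# I/O: NIfTI (spacing in the affine) and multipage TIFF + JSON sidecar.
# ---------------------------------------------------------------------------


def save_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as ``.nii``/``.nii.gz`` or ``.tif`` + JSON sidecar."""
    path = Path(path)
    data = volume.voxels.astype(np.uint8) if volume.voxels.dtype == bool else volume.voxels
    if path.suffix in {".nii", ".gz"} or str(path).endswith(".nii.gz"):
        affine = np.diag(list(volume.spacing_mm) + [1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    elif path.suffix in {".tif", ".tiff"}:
        # pages along z: transpose to (z, y, x)
        tifffile.imwrite(path, np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"spacing_mm": list(volume.spacing_mm), "origin_mm": list(volume.origin_mm)}
            )
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return path


def load_volume(path: str | Path, as_mask: bool = False) -> Volume:
    """Read a volume written by :func:`save_volume`."""
    path = Path(path)
    if path.suffix == ".nii" or str(path).endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif path.suffix in {".tif", ".tiff"}:
        data = np.transpose(tifffile.imread(path), (2, 1, 0))
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        spacing = tuple(meta["spacing_mm"])
        origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    cls = MaskVolume if as_mask else Volume
    return cls(data.astype(bool) if as_mask else data, spacing, origin)
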