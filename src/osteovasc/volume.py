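"""Volumetric containers shared by the whole pipeline.

The central currency is :class:`LabelVolume`, a dense 3D integer grid over the
four-class vocabulary background / bone / vessel / metastasis together with the
physical voxel size in micrometres.  Axis order is slices-first ``(z, y, x)``,
matching stack-of-TIFF acquisition order; ``voxel_size_um`` follows the same
axis order and may be anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BACKGROUND",
    "BONE",
    "VESSEL",
    "METASTASIS",
    "CLASS_NAMES",
    "FOREGROUND_CLASSES",
    "LabelVolume",
    "IntensityVolume",
]

BACKGROUND = 0
BONE = 1
VESSEL = 2
METASTASIS = 3

CLASS_NAMES = {BACKGROUND: "background", BONE: "bone", VESSEL: "vessel", METASTASIS: "metastasis"}
FOREGROUND_CLASSES = (BONE, VESSEL, METASTASIS)


def _check_voxel_size(voxel_size_um) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in np.broadcast_to(voxel_size_um, (3,)))
    if any(not np.isfinite(v) or v <= 0 for v in vs):
        raise ValueError(f"voxel sizes must be positive and finite, got {vs}")
    return vs


@dataclass
class LabelVolume:
    """A 3D class-label grid with physical voxel size.

    Parameters
    ----------
    data
        Integer array of shape ``(nz, ny, nx)`` with values in
        ``{0: background, 1: bone, 2: vessel, 3: metastasis}``.
    voxel_size_um
        Physical voxel edge lengths in µm, per axis ``(z, y, x)``; a scalar is
        broadcast to all three axes.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (3.5, 3.5, 3.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"label volume needs >= 2 voxels per axis, got {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must be integer-typed, got {self.data.dtype}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)
        bad = np.setdiff1d(np.unique(self.data), list(CLASS_NAMES))
        if bad.size:
            raise ValueError(f"unknown class id(s) {bad.tolist()}; vocabulary is {sorted(CLASS_NAMES)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    def mask(self, class_id: int) -> np.ndarray:
        """Binary mask of one class."""
        if class_id not in CLASS_NAMES:
            raise ValueError(f"unknown class id {class_id}")
        return self.data == class_id

    def class_counts(self) -> dict[int, int]:
        """Voxel count per class id (zero for absent classes)."""
        counts = np.bincount(self.data.ravel(), minlength=len(CLASS_NAMES))
        return {cid: int(counts[cid]) for cid in CLASS_NAMES}


@dataclass
class IntensityVolume:
    """A 3D grayscale grid emulating µCT attenuation, with voxel size in µm."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (3.5, 3.5, 3.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got shape {self.data.shape}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape
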