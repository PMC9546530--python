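"""Core in-memory containers: intensity volumes and label atlases.

Arrays are indexed ``(z, y, x)`` and voxel sizes are physical micrometres
``(dz, dy, dx)``. Voxel ``(i, j, k)`` spans the half-open physical box
``[i*dz, (i+1)*dz) x [j*dy, (j+1)*dy) x [k*dx, (k+1)*dx)``, so the centre of
voxel ``i`` along an axis with spacing ``d`` sits at ``(i + 0.5) * d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel tags used throughout the pipeline.
CHANNEL_GREEN = "syp_egfp"
CHANNEL_RED = "tdtomato"

UM3_PER_MM3 = 1e9


@dataclass
class ImageVolume:
    """A 3D intensity grid with physical voxel spacing and a channel tag.

    Parameters
    ----------
    data:
        Non-negative intensity array of shape ``(nz, ny, nx)``.
    voxel_size:
        Physical voxel spacing ``(dz, dy, dx)`` in micrometres.
    channel:
        ``"syp_egfp"`` (green puncta channel) or ``"tdtomato"`` (red
        fiber/soma channel).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = CHANNEL_GREEN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"volume shape must be >= (1,1,1), got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent ``(z, y, x)`` of the volume in micrometres."""
        return tuple(n * d for n, d in zip(self.data.shape, self.voxel_size))

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class LabelAtlas:
    """An integer region-label grid plus a region ontology.

    Label 0 means outside-brain background; labels >= 1 are brain regions.
    ``ontology`` maps each region label to ``{"acronym": ..., "name": ...}``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    ontology: dict[int, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"atlas must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"atlas labels must be integers, got {self.labels.dtype}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.ontology = {int(k): dict(v) for k, v in self.ontology.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def region_labels(self) -> list[int]:
        """Sorted list of nonzero labels present in the grid."""
        present = np.unique(self.labels)
        return [int(v) for v in present if v != 0]

    def acronym(self, label: int) -> str:
        return self.ontology.get(int(label), {}).get("acronym", str(int(label)))

    def region_voxel_count(self, label: int) -> int:
        n = int(np.count_nonzero(self.labels == int(label)))
        if n == 0:
            raise KeyError(f"label {label} not present in atlas")
        return n

    def region_volume_mm3(self, label: int) -> float:
        """Physical volume of a region in mm^3 (1 mm^3 = 1e9 um^3)."""
        return self.region_voxel_count(label) * self.voxel_volume_um3 / UM3_PER_MM3

    def label_at(self, z_um: float, y_um: float, x_um: float) -> int:
        """Label of the voxel containing a physical coordinate (floor rule)."""
        idx = []
        for c, d, n in zip((z_um, y_um, x_um), self.voxel_size, self.labels.shape):
            i = int(np.floor(c / d))
            if i < 0 or i >= n:
                return 0
            idx.append(i)
        return int(self.labels[tuple(idx)])
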