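"""Volumetric containers for OCT intensity data and segmentation labels.

Axis convention, used everywhere in the package: arrays are indexed
``(z, y, x)`` where ``z`` is optical depth (the A-scan direction), ``y`` the
fast lateral axis and ``x`` the slow lateral axis.  Depth extent is optical
path length, not geometric distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed five-class semantic map for thick-skin OCT volumes.
CLASS_NAMES: dict[int, str] = {
    1: "background",
    2: "upper_sc",
    3: "ordered_sc",
    4: "epidermis",
    5: "dermis",
}

N_CLASSES = 5


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel grid counts plus physical extents in millimetres.

    ``extent_z_mm`` is the optical depth extent: dividing by a tissue
    refractive index converts layer spans to geometric thickness.
    """

    n_z: int
    n_y: int
    n_x: int
    extent_z_mm: float = 1.2
    extent_y_mm: float = 3.0
    extent_x_mm: float = 3.0

    def __post_init__(self) -> None:
        if min(self.n_z, self.n_y, self.n_x) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.extent_z_mm, self.extent_y_mm, self.extent_x_mm) <= 0:
            raise ValueError("physical extents must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, self.n_y, self.n_x)

    @property
    def dz_opt_mm(self) -> float:
        """Optical voxel depth in mm."""
        return self.extent_z_mm / self.n_z

    @property
    def dz_opt_um(self) -> float:
        """Optical voxel depth in micrometres."""
        return 1000.0 * self.extent_z_mm / self.n_z

    def to_dict(self) -> dict:
        return {
            "n_z": self.n_z,
            "n_y": self.n_y,
            "n_x": self.n_x,
            "extent_z_mm": self.extent_z_mm,
            "extent_y_mm": self.extent_y_mm,
            "extent_x_mm": self.extent_x_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(
            n_z=int(d["n_z"]),
            n_y=int(d["n_y"]),
            n_x=int(d["n_x"]),
            extent_z_mm=float(d["extent_z_mm"]),
            extent_y_mm=float(d["extent_y_mm"]),
            extent_x_mm=float(d["extent_x_mm"]),
        )


#: Default acquisition geometry of the imaging system: 256x512x512 voxels
#: spanning 1.2x3.0x3.0 mm.
DEFAULT_GEOMETRY = VoxelGeometry(256, 512, 512, 1.2, 3.0, 3.0)


@dataclass
class OCTVolume:
    """A 3D OCT backscatter-intensity volume in relative units."""

    intensity: np.ndarray
    geometry: VoxelGeometry
    identifier: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.ndim != 3:
            raise ValueError(f"intensity must be 3D, got ndim={self.intensity.ndim}")
        if self.intensity.shape != self.geometry.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.intensity.min() < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


@dataclass
class LabelVolume:
    """Integer class labels 1..5 on the same grid as an :class:`OCTVolume`.

    Classes are stacked in depth order along every lateral column
    (background above skin, then the two stratum-corneum sub-layers, the
    cellular epidermis and finally the dermis down to the grid bottom).
    """

    labels: np.ndarray
    geometry: VoxelGeometry
    identifier: str = ""
    class_names: dict[int, str] = field(default_factory=lambda: dict(CLASS_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if self.labels.shape != self.geometry.shape:
            raise ValueError(
                f"labels shape {self.labels.shape} != geometry {self.geometry.shape}"
            )
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < 1 or hi > N_CLASSES:
            raise ValueError(f"labels must lie in 1..{N_CLASSES}, got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def is_depth_monotone(self) -> bool:
        """True if class indices never decrease with depth in any column."""
        return bool(np.all(np.diff(self.labels.astype(np.int16), axis=0) >= 0))


@dataclass
class BoundarySurface:
    """Depth map z(y, x) of the upper boundary of one layer.

    Depths are real-valued while surfaces are being estimated; they are
    rounded half-up only when labels are assigned.
    """

    layer: int
    z_of: np.ndarray
    flagged: np.ndarray | None = None  # columns where no threshold crossing was found

    def __post_init__(self) -> None:
        self.z_of = np.asarray(self.z_of, dtype=np.float64)
        if self.z_of.ndim != 2:
            raise ValueError("z_of must be a 2D (y, x) map")
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool)
            if self.flagged.shape != self.z_of.shape:
                raise ValueError("flagged shape must match z_of")

    def rounded(self) -> np.ndarray:
        """Half-up rounding to integer voxel indices."""
        return np.floor(self.z_of + 0.5).astype(np.int64)


def round_half_up(z: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(z, dtype=np.float64) + 0.5).astype(np.int64)


def labels_from_surfaces(
    surfaces: list[BoundarySurface], geometry: VoxelGeometry
) -> LabelVolume:
    """Assign labels per column from the four upper-boundary surfaces.

    Class 1 above surface 2; class i on [z_i, z_{i+1}); class 5 from z_5 to
    the grid bottom.  Surfaces are rounded half-up and clamped to be
    non-decreasing in layer order.
    """
    if len(surfaces) != 4:
        raise ValueError("expected surfaces for layers 2..5")
    n_z, n_y, n_x = geometry.shape
    zmaps = []
    prev = np.zeros((n_y, n_x), dtype=np.int64)
    for s in sorted(surfaces, key=lambda s: s.layer):
        z = np.clip(s.rounded(), 0, n_z)
        z = np.maximum(z, prev)
        zmaps.append(z)
        prev = z
    depth = np.arange(n_z, dtype=np.int64)[:, None, None]
    labels = np.ones((n_z, n_y, n_x), dtype=np.uint8)
    for cls, z in zip((2, 3, 4, 5), zmaps):
        labels[depth >= z[None, :, :]] = cls
    return LabelVolume(labels, geometry)


def central_crop(vol: OCTVolume | LabelVolume, target_x: int) -> OCTVolume | LabelVolume:
    """Crop the slow lateral axis x to its central ``target_x`` voxels.

    The probe distorts texture near B-scan borders, so only a central part of
    each acquired volume is analysed (512 -> 256 along x by default).  For odd
    remainders the extra voxel is trimmed from the high-index side.  The
    per-voxel physical size along x is preserved; z and y are untouched.
    """
    g = vol.geometry
    if target_x > g.n_x:
        raise ValueError(f"target_x={target_x} exceeds n_x={g.n_x}")
    if target_x < 1:
        raise ValueError("target_x must be >= 1")
    lo = (g.n_x - target_x) // 2
    hi = lo + target_x
    new_geom = replace(
        g, n_x=target_x, extent_x_mm=g.extent_x_mm * target_x / g.n_x
    )
    if isinstance(vol, LabelVolume):
        return LabelVolume(vol.labels[:, :, lo:hi].copy(), new_geom, vol.identifier)
    return OCTVolume(vol.intensity[:, :, lo:hi].copy(), new_geom, vol.identifier)
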