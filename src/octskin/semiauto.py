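"""Semi-automatic primary segmentation of thick-skin OCT volumes.

For each layer i = 2..5 a cuboid region M_i known to lie inside the layer is
selected; the detection threshold is built from its signal statistics,

    I_t^i = mean_{M_i}(I) - alpha_i * std_{M_i}(I),

with alpha_i an empirically selected, possibly negative multiplier.  Scanning
each lateral column downward from just below the previous layer's boundary,
the first voxel crossing the threshold (upward for bright layers, downward for
dark ones) marks the layer's upper boundary.  The boundary z-map is median
filtered (w_i = 11 by default), and the image below the first boundary is
median filtered in 3D to suppress speckle before deeper layers are detected.

This automates the expert-in-the-loop workflow in which a specialist re-selects
alpha_i / w_i until the boundary matches visual inspection: here the
parameters live in explicit presets and the result is validated against
phantom ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import (
    BoundarySurface,
    LabelVolume,
    OCTVolume,
    labels_from_surfaces,
)

LAYERS = (2, 3, 4, 5)

#: Threshold-crossing direction for each layer's upper boundary, following the
#: bright/dark/bright/dark contrast sequence of thick skin.
DEFAULT_CROSSING = {2: "rising", 3: "falling", 4: "rising", 5: "falling"}


@dataclass(frozen=True)
class LayerROI:
    """Half-open cuboid [z0, z1) x [y0, y1) x [x0, x1) inside one layer."""

    layer: int
    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        if not (self.z0 < self.z1 and self.y0 < self.y1 and self.x0 < self.x1):
            raise ValueError("ROI cuboid must be non-empty")
        if min(self.z0, self.y0, self.x0) < 0:
            raise ValueError("ROI bounds must be non-negative")

    def extract(self, vol: OCTVolume) -> np.ndarray:
        n_z, n_y, n_x = vol.shape
        if self.z1 > n_z or self.y1 > n_y or self.x1 > n_x:
            raise ValueError(f"ROI {self} exceeds volume shape {vol.shape}")
        return vol.intensity[self.z0 : self.z1, self.y0 : self.y1, self.x0 : self.x1]


@dataclass(frozen=True)
class SemiAutoParams:
    """Per-layer detection parameters.

    ``alpha`` are the threshold multipliers (negative values raise the
    threshold above the ROI mean, which is what falling crossings into dark
    layers need); ``w`` the odd median window for the boundary z-map;
    ``crossing`` the threshold-crossing direction; ``despeckle_window`` the odd
    3D median window applied below each detected boundary.
    """

    alpha: dict[int, float] = field(
        default_factory=lambda: {2: 2.0, 3: -2.0, 4: 0.7, 5: -2.0}
    )
    w: dict[int, int] = field(default_factory=lambda: {i: 11 for i in LAYERS})
    crossing: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CROSSING))
    despeckle_window: int = 3

    def __post_init__(self) -> None:
        for i in LAYERS:
            if self.w[i] < 1 or self.w[i] % 2 == 0:
                raise ValueError(f"w[{i}] must be odd and >= 1")
            if self.crossing[i] not in ("rising", "falling"):
                raise ValueError("crossing must be 'rising' or 'falling'")
        if self.despeckle_window < 1 or self.despeckle_window % 2 == 0:
            raise ValueError("despeckle_window must be odd and >= 1")

    @classmethod
    def noise_free(cls) -> "SemiAutoParams":
        """Preset for noise-free images: no smoothing or despeckling needed."""
        return cls(
            alpha={2: 2.0, 3: -30.0, 4: 0.5, 5: -4.0},
            w={i: 1 for i in LAYERS},
            despeckle_window=1,
        )


def layer_threshold(vol: OCTVolume, roi: LayerROI, alpha: float) -> float:
    """Threshold I_t = mean(ROI) - alpha * population SD(ROI)."""
    block = roi.extract(vol)
    return float(block.mean() - alpha * block.std())


def detect_upper_boundary(
    vol: OCTVolume,
    threshold: float,
    crossing: str = "rising",
    z_start: BoundarySurface | np.ndarray | None = None,
) -> BoundarySurface:
    """First threshold crossing along each column, scanning downward in z.

    Columns with no crossing get the deepest scanned index and are flagged.
    """
    if crossing not in ("rising", "falling"):
        raise ValueError("crossing must be 'rising' or 'falling'")
    I = vol.intensity
    n_z, n_y, n_x = I.shape
    if z_start is None:
        start = np.zeros((n_y, n_x), dtype=np.int64)
    else:
        start = z_start.rounded() if isinstance(z_start, BoundarySurface) else np.asarray(
            z_start, dtype=np.int64
        )
        if start.min() < 0 or start.max() >= n_z:
            raise ValueError("z_start must lie within the grid")
    hit = I >= threshold if crossing == "rising" else I <= threshold
    # mask out voxels above the per-column scan start
    depth = np.arange(n_z)[:, None, None]
    hit &= depth >= start[None, :, :]
    any_hit = hit.any(axis=0)
    z = np.where(any_hit, hit.argmax(axis=0), n_z - 1)
    return BoundarySurface(layer=0, z_of=z.astype(np.float64), flagged=~any_hit)


def smooth_surface(surface: BoundarySurface, w: int, n_z: int | None = None) -> BoundarySurface:
    """2D median filter (w x w lateral window, reflected borders) on the z-map."""
    if w % 2 == 0:
        raise ValueError("median window must be odd")
    z = surface.z_of if w == 1 else ndimage.median_filter(
        surface.z_of, size=w, mode="reflect"
    )
    if n_z is not None:
        z = np.clip(z, 0, n_z - 1)
    return BoundarySurface(surface.layer, z, surface.flagged)


def despeckle_below(vol: OCTVolume, surface: BoundarySurface, window: int) -> OCTVolume:
    """3D median filter applied only at voxels with z >= surface; above untouched."""
    if window % 2 == 0:
        raise ValueError("median window must be odd")
    if window == 1:
        return vol
    filtered = ndimage.median_filter(vol.intensity, size=window, mode="reflect")
    depth = np.arange(vol.shape[0])[:, None, None]
    below = depth >= surface.rounded()[None, :, :]
    out = np.where(below, filtered, vol.intensity).astype(np.float32)
    return OCTVolume(out, vol.geometry, vol.identifier)


def run_semiauto(
    vol: OCTVolume,
    rois: dict[int, LayerROI] | list[LayerROI],
    params: SemiAutoParams | None = None,
) -> tuple[LabelVolume, list[BoundarySurface]]:
    """Iterate threshold -> detect -> smooth -> despeckle over layers 2..5.

    Layer i's scan starts strictly below layer i-1's smoothed boundary;
    surfaces are clamped to be non-decreasing across layers, and final labels
    are assigned per column (class 1 above surface 2, class i on
    [z_i, z_{i+1}), class 5 to the bottom).
    """
    params = params or SemiAutoParams()
    roi_map = (
        {r.layer: r for r in rois} if not isinstance(rois, dict) else dict(rois)
    )
    missing = [i for i in LAYERS if i not in roi_map]
    if missing:
        raise ValueError(f"missing ROI for layers {missing}")

    n_z = vol.shape[0]
    work = vol
    surfaces: list[BoundarySurface] = []
    prev: np.ndarray | None = None
    for layer in LAYERS:
        thr = layer_threshold(work, roi_map[layer], params.alpha[layer])
        start = None if prev is None else np.minimum(prev + 1, n_z - 1)
        raw = detect_upper_boundary(work, thr, params.crossing[layer], z_start=start)
        raw.layer = layer
        smooth = smooth_surface(raw, params.w[layer], n_z=n_z)
        if prev is not None:
            smooth.z_of = np.maximum(smooth.z_of, prev)
        surfaces.append(smooth)
        prev = smooth.rounded()
        if layer == 2:
            work = despeckle_below(work, smooth, params.despeckle_window)
    labels = labels_from_surfaces(surfaces, vol.geometry)
    labels.identifier = vol.identifier
    return labels, surfaces


def rois_for_phantom(params) -> dict[int, "LayerROI"]:
    """ROIs centred in each layer of a :class:`~octskin.phantom.PhantomParams`
    configuration (the expected layer positions, not the realized ones)."""
    return default_phantom_rois(
        params.gap_depth_vox,
        {i: params.optical_thickness_vox(i) for i in (2, 3, 4)},
        params.geometry.shape,
    )


def default_phantom_rois(
    gap_depth_vox: float,
    optical_thickness_vox: dict[int, float],
    shape: tuple[int, int, int],
    margin_frac: float = 0.3,
) -> dict[int, LayerROI]:
    """Build ROIs centred in each layer of a phantom-like geometry.

    Each cuboid spans the central lateral region and the central
    (1 - 2*margin_frac) fraction of the layer's depth — the practical analogue
    of an operator picking a box "guaranteed to belong to the given layer".
    """
    n_z, n_y, n_x = shape
    y0, y1 = n_y // 4, 3 * n_y // 4
    x0, x1 = n_x // 4, 3 * n_x // 4
    rois = {}
    top = gap_depth_vox
    for layer in (2, 3, 4):
        t = optical_thickness_vox[layer]
        z0 = int(round(top + margin_frac * t))
        z1 = int(round(top + (1 - margin_frac) * t))
        z1 = max(z1, z0 + 1)
        rois[layer] = LayerROI(layer, z0, min(z1, n_z), y0, y1, x0, x1)
        top += t
    # dermis: from just below surface 5 to a band ~2 layer-thicknesses deep
    z0 = int(round(top + 6))
    z1 = min(n_z, int(round(top + 40)))
    rois[5] = LayerROI(5, z0, max(z1, z0 + 1), y0, y1, x0, x1)
    return rois
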