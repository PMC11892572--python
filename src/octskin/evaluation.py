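"""Segmentation quality and morphometry: Dice overlap and layer thickness.

The Sørensen–Dice coefficient per class i is

    DSC_i = 2 n(K_true = K_segm = i) / (n(K_true = i) + n(K_segm = i)),

in [0, 1], 1 for a perfect match; a class absent from both volumes scores 1 by
convention.  Layer thickness is estimated per lateral column as the layer's
voxel count times the optical voxel depth, divided by the tissue refractive
index (1.4 for skin) to convert optical path to geometric thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabelVolume, N_CLASSES, VoxelGeometry


@dataclass
class DSCReport:
    """Per-class Dice coefficients with the underlying voxel counts."""

    dsc: dict[int, float]
    n_true: dict[int, int]
    n_segm: dict[int, int]
    n_match: dict[int, int]

    def mean_tissue(self) -> float:
        """Mean DSC over the four tissue classes 2..5 (background excluded)."""
        return float(np.mean([self.dsc[i] for i in range(2, N_CLASSES + 1)]))


def dice(true: LabelVolume, segm: LabelVolume) -> DSCReport:
    """Per-class Sørensen–Dice coefficients between two label volumes."""
    if true.shape != segm.shape:
        raise ValueError(f"shape mismatch: {true.shape} vs {segm.shape}")
    t = true.labels.ravel()
    s = segm.labels.ravel()
    n_true = np.bincount(t, minlength=N_CLASSES + 1)
    n_segm = np.bincount(s, minlength=N_CLASSES + 1)
    match = t[t == s]
    n_match = np.bincount(match, minlength=N_CLASSES + 1)
    dsc = {}
    for i in range(1, N_CLASSES + 1):
        denom = int(n_true[i] + n_segm[i])
        dsc[i] = 1.0 if denom == 0 else 2.0 * int(n_match[i]) / denom
    return DSCReport(
        dsc=dsc,
        n_true={i: int(n_true[i]) for i in range(1, N_CLASSES + 1)},
        n_segm={i: int(n_segm[i]) for i in range(1, N_CLASSES + 1)},
        n_match={i: int(n_match[i]) for i in range(1, N_CLASSES + 1)},
    )


def layer_thickness(
    labels: LabelVolume,
    layer: int,
    geometry: VoxelGeometry | None = None,
    n_refr: float = 1.4,
) -> tuple[np.ndarray, float]:
    """Per-column geometric thickness of a layer in micrometres, and its mean.

    thickness(y, x) = count(labels == layer along z) * dz_opt_um / n_refr.
    Columns without any voxel of the layer are excluded from the mean (NaN in
    the map).  The dermis (class 5) is rejected: its lower border lies beyond
    the imaging depth, so its voxel count is not a thickness.
    """
    if layer not in (2, 3, 4):
        raise ValueError(
            "thickness is defined for layers 2..4; the dermis extends past the grid"
        )
    g = geometry or labels.geometry
    counts = (labels.labels == layer).sum(axis=0).astype(np.float64)
    thick = counts * g.dz_opt_um / n_refr
    thick[counts == 0] = np.nan
    valid = thick[~np.isnan(thick)]
    mean = float(valid.mean()) if valid.size else float("nan")
    return thick, mean


@dataclass
class ThicknessReport:
    """Cohort thickness statistics (M±SD over per-volume means) for one layer."""

    layer: int
    mean_um: float
    sd_um: float | None
    per_volume_um: list[float]
    refractive_index: float
    delta_z_opt_um: float


def cohort_thickness(
    label_volumes: list[LabelVolume],
    layer: int,
    geometry: VoxelGeometry | None = None,
    n_refr: float = 1.4,
) -> ThicknessReport:
    """Mean and sample SD of per-volume mean thickness across a cohort."""
    if not label_volumes:
        raise ValueError("need at least one label volume")
    g = geometry or label_volumes[0].geometry
    per_vol = [layer_thickness(lv, layer, g, n_refr)[1] for lv in label_volumes]
    arr = np.asarray(per_vol, dtype=np.float64)
    sd = float(arr.std(ddof=1)) if len(per_vol) >= 2 else None
    return ThicknessReport(
        layer=layer,
        mean_um=float(arr.mean()),
        sd_um=sd,
        per_volume_um=per_vol,
        refractive_index=n_refr,
        delta_z_opt_um=g.dz_opt_um,
    )
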