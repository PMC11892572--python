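"""Block decomposition of volumes and Gaussian-blended block inference.

Training blocks are either single B-scans (256x512x1: one per slow-axis
index, 256 per cropped volume) or disjoint 256x64x64 tiles (32 per volume).
For 3D inference the volume is split into overlapping 256x64x64 blocks; each
voxel's per-class confidence is the sum over covering blocks of the block's
softmax score weighted by a Gaussian of the lateral distance to the block
centre (sigma = 16 voxels), which removes seams at block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.unet import UNet, softmax
from .volume import LabelVolume, OCTVolume


@dataclass(frozen=True)
class BlendParams:
    """Gaussian blending weights: w = exp(-d^2 / (2 sigma^2)).

    ``distance`` selects the subspace for d: ``lateral`` (default — blocks
    span the full depth, so overlap is lateral only) or ``full3d``.
    """

    sigma_vox: float = 16.0
    distance: str = "lateral"
    normalize_scores: bool = True

    def __post_init__(self) -> None:
        if self.sigma_vox <= 0:
            raise ValueError("sigma_vox must be > 0")
        if self.distance not in ("lateral", "full3d"):
            raise ValueError("distance must be 'lateral' or 'full3d'")


@dataclass
class BlockGrid:
    """A set of equally shaped blocks at listed origin corners."""

    block_shape: tuple[int, int, int]
    stride: tuple[int, int, int]
    origins: list[tuple[int, int, int]]
    volume_shape: tuple[int, int, int]
    mode: str  # slices_2d | tiles_3d_disjoint | tiles_3d_overlap

    def __len__(self) -> int:
        return len(self.origins)

    def extract(self, vol: OCTVolume | np.ndarray, i: int) -> np.ndarray:
        data = vol.intensity if isinstance(vol, OCTVolume) else vol
        o, s = self.origins[i], self.block_shape
        return data[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]]

    def coverage(self) -> np.ndarray:
        """Per-voxel count of covering blocks."""
        cov = np.zeros(self.volume_shape, dtype=np.int32)
        s = self.block_shape
        for o in self.origins:
            cov[o[0] : o[0] + s[0], o[1] : o[1] + s[1], o[2] : o[2] + s[2]] += 1
        return cov


def split_2d(vol: OCTVolume) -> BlockGrid:
    """One block per slow-axis index x: n_x B-scans of shape (n_z, n_y, 1)."""
    n_z, n_y, n_x = vol.shape
    return BlockGrid(
        block_shape=(n_z, n_y, 1),
        stride=(n_z, n_y, 1),
        origins=[(0, 0, x) for x in range(n_x)],
        volume_shape=vol.shape,
        mode="slices_2d",
    )


def split_3d_disjoint(vol: OCTVolume, block_shape: tuple[int, int, int]) -> BlockGrid:
    """Disjoint lateral tiling into full-depth blocks."""
    n_z, n_y, n_x = vol.shape
    b_z, b_y, b_x = block_shape
    if b_z != n_z:
        raise ValueError(f"blocks must span the full depth ({n_z}), got b_z={b_z}")
    if n_y % b_y or n_x % b_x:
        raise ValueError(
            f"lateral dims {(n_y, n_x)} not divisible by block {(b_y, b_x)}"
        )
    origins = [
        (0, y, x)
        for y in range(0, n_y, b_y)
        for x in range(0, n_x, b_x)
    ]
    return BlockGrid(block_shape, block_shape, origins, vol.shape, "tiles_3d_disjoint")


def _axis_origins(n: int, b: int, stride: int) -> list[int]:
    """Stride lattice with the last origin clamped inward for full coverage."""
    if b >= n:
        return [0]
    out = list(range(0, n - b + 1, stride))
    if out[-1] != n - b:
        out.append(n - b)
    return out


def split_3d_overlap(
    vol: OCTVolume,
    block_shape: tuple[int, int, int],
    stride: tuple[int, int] = (32, 32),
) -> BlockGrid:
    """Overlapping full-depth blocks on a lateral stride lattice.

    Every voxel is covered by at least one block; the last row/column of
    blocks is shifted inward when the stride does not divide evenly.
    """
    n_z, n_y, n_x = vol.shape
    b_z, b_y, b_x = block_shape
    s_y, s_x = stride
    if s_y <= 0 or s_x <= 0:
        raise ValueError("stride must be positive")
    if s_y > b_y or s_x > b_x:
        raise ValueError("stride must not exceed block size (coverage gaps)")
    if b_z != n_z:
        raise ValueError(f"blocks must span the full depth ({n_z}), got b_z={b_z}")
    if b_y > n_y or b_x > n_x:
        raise ValueError("block larger than volume")
    origins = [
        (0, y, x)
        for y in _axis_origins(n_y, b_y, s_y)
        for x in _axis_origins(n_x, b_x, s_x)
    ]
    return BlockGrid(block_shape, (b_z, s_y, s_x), origins, vol.shape, "tiles_3d_overlap")


def gaussian_weight(
    voxel: tuple[int, int, int],
    origin: tuple[int, int, int],
    block_shape: tuple[int, int, int],
    params: BlendParams | None = None,
) -> float:
    """Blending weight of one voxel within one block; 1.0 at the centre."""
    params = params or BlendParams()
    for v, o, s in zip(voxel, origin, block_shape):
        if not (o <= v < o + s):
            raise ValueError(f"voxel {voxel} outside block at {origin} shape {block_shape}")
    center = [o + (s - 1) / 2.0 for o, s in zip(origin, block_shape)]
    deltas = [v - c for v, c in zip(voxel, center)]
    if params.distance == "lateral":
        deltas = deltas[1:]
    d2 = float(sum(d * d for d in deltas))
    return float(np.exp(-d2 / (2.0 * params.sigma_vox**2)))


def _block_weight_map(
    block_shape: tuple[int, int, int], params: BlendParams
) -> np.ndarray:
    """Weight of every voxel of a block (independent of the block's origin)."""
    axes = []
    for s in block_shape:
        c = (s - 1) / 2.0
        axes.append((np.arange(s) - c) ** 2)
    z2, y2, x2 = axes
    if params.distance == "lateral":
        z2 = np.zeros_like(z2)
    d2 = z2[:, None, None] + y2[None, :, None] + x2[None, None, :]
    return np.exp(-d2 / (2.0 * params.sigma_vox**2)).astype(np.float64)


def blend_scores(
    score_blocks: list[np.ndarray],
    grid: BlockGrid,
    params: BlendParams | None = None,
) -> np.ndarray:
    """Gaussian-weighted average of per-block class scores over the volume.

    Each entry of ``score_blocks`` has shape (n_classes, *block_shape).
    Returns (n_classes, *volume_shape): per voxel and class,
    sum_b w_b * score_b / sum_b w_b over the covering blocks.
    """
    params = params or BlendParams()
    if len(score_blocks) != len(grid):
        raise ValueError("one score block required per grid block")
    n_classes = score_blocks[0].shape[0]
    acc = np.zeros((n_classes,) + grid.volume_shape, dtype=np.float64)
    wsum = np.zeros(grid.volume_shape, dtype=np.float64)
    w = _block_weight_map(grid.block_shape, params)
    s = grid.block_shape
    for o, scores in zip(grid.origins, score_blocks):
        sl = (
            slice(o[0], o[0] + s[0]),
            slice(o[1], o[1] + s[1]),
            slice(o[2], o[2] + s[2]),
        )
        acc[(slice(None),) + sl] += w * scores
        wsum[sl] += w
    if np.any(wsum == 0):
        raise RuntimeError("grid does not cover the volume")
    return acc / wsum


def blend_predict(
    vol: OCTVolume,
    net: UNet,
    grid: BlockGrid | None = None,
    params: BlendParams | None = None,
    batch_size: int = 8,
    normalize: "callable | None" = None,
) -> LabelVolume:
    """Segment a volume block-wise and recombine into a label volume.

    2D slice grids are assembled directly (disjoint slices); overlapping 3D
    grids are blended with Gaussian weights.  Per-block scores are softmax
    normalized before weighting so they are comparable across blocks (raw-score
    blending via ``BlendParams(normalize_scores=False)``).
    """
    params = params or BlendParams()
    if grid is None:
        grid = split_2d(vol) if net.config.dims == 2 else split_3d_overlap(
            vol, (vol.shape[0], 64, 64)
        )
    data = vol.intensity if normalize is None else normalize(vol.intensity)
    score_blocks: list[np.ndarray] = []
    if net.config.dims == 2:
        # batch the (n_z, n_y) faces of each block
        blocks = [grid.extract(data, i) for i in range(len(grid))]
        for i0 in range(0, len(blocks), batch_size):
            batch = np.stack(
                [b[:, :, 0] for b in blocks[i0 : i0 + batch_size]]
            )[:, None]
            out = net.forward(batch, train=False)
            for j in range(out.shape[0]):
                score_blocks.append(out[j][..., None])
    else:
        for i in range(len(grid)):
            out = net.forward(grid.extract(data, i)[None, None], train=False)
            score_blocks.append(out[0])
    if params.normalize_scores:
        score_blocks = [softmax(s, axis=0) for s in score_blocks]
    conf = blend_scores(score_blocks, grid, params)
    labels = (np.argmax(conf, axis=0) + 1).astype(np.uint8)
    return LabelVolume(labels, vol.geometry, identifier=vol.identifier)
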