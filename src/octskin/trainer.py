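"""Training of the 2D/3D U-Nets with leave-one-out cross-validation.

Per-voxel softmax cross-entropy over all five classes is minimized with Adam
(learning rate 0.001, betas (0.9, 0.98)).  Of the available volumes a seeded
subset is held out entirely for testing; each remaining volume serves as the
validation object of exactly one fold, and the fold with the best mean tissue
DSC during validation is selected for the test sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .blocks import BlendParams, blend_predict, split_2d, split_3d_disjoint
from .evaluation import dice
from .nn.unet import Adam, UNet, UNetConfig, build_unet, cross_entropy
from .volume import LabelVolume, OCTVolume


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    betas: tuple[float, float] = (0.9, 0.98)
    epochs: int = 40
    batch_size: int = 8
    max_steps: int | None = None  # cap on optimizer steps (None = no cap)
    seed: int = 0
    augment_elastic: bool = False
    norm_percentile: float = 99.0
    block_shape_3d: tuple[int, int, int] | None = None  # default: full depth x 64 x 64

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        b1, b2 = self.betas
        if not (0 <= b1 < 1 and 0 <= b2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class CVPlan:
    train_volume_ids: list[str]
    test_volume_ids: list[str]
    folds: list[tuple[list[str], str]]  # (train ids, validation id)


@dataclass
class FoldResult:
    fold_id: int
    net: UNet
    val_dsc: dict[int, float]
    mean_tissue_dsc: float
    loss_history: list[float] = field(default_factory=list)


def make_cv_plan(volume_ids: list[str], n_test: int, seed: int = 0) -> CVPlan:
    """Hold out ``n_test`` volumes at random; leave-one-out folds on the rest."""
    if n_test >= len(volume_ids):
        raise ValueError("n_test must be smaller than the number of volumes")
    rng = np.random.default_rng(seed)
    ids = list(volume_ids)
    test = sorted(rng.choice(len(ids), size=n_test, replace=False).tolist())
    test_ids = [ids[i] for i in test]
    train_ids = [v for v in ids if v not in test_ids]
    folds = [([t for t in train_ids if t != v], v) for v in train_ids]
    return CVPlan(train_ids, test_ids, folds)


def percentile_normalize(intensity: np.ndarray, p: float = 99.0) -> np.ndarray:
    """Scale a volume by its p-th intensity percentile (robust to speckle tails)."""
    scale = np.percentile(intensity, p)
    return (intensity / max(scale, 1e-12)).astype(np.float32)


def _elastic_2d(img: np.ndarray, lab: np.ndarray, rng: np.random.Generator,
                alpha: float = 8.0, sigma: float = 8.0):
    """Random smooth warping of a B-scan and its labels (optional augmentation)."""
    from scipy import ndimage

    h, w = img.shape
    dz = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma) * alpha
    zz, yy = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [zz + dz, yy + dy]
    img_w = ndimage.map_coordinates(img, coords, order=1, mode="reflect")
    lab_w = ndimage.map_coordinates(lab, coords, order=0, mode="reflect")
    return img_w, lab_w


def _training_blocks(
    data: dict[str, tuple[OCTVolume, LabelVolume]],
    ids: list[str],
    dims: int,
    cfg: TrainConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalized (intensity, labels) training blocks from the listed volumes."""
    blocks = []
    for vid in ids:
        vol, lab = data[vid]
        norm = percentile_normalize(vol.intensity, cfg.norm_percentile)
        if dims == 2:
            grid = split_2d(vol)
            for i in range(len(grid)):
                o = grid.origins[i]
                blocks.append((norm[:, :, o[2]], lab.labels[:, :, o[2]]))
        else:
            shape = cfg.block_shape_3d or (vol.shape[0], 64, 64)
            grid = split_3d_disjoint(vol, shape)
            for i in range(len(grid)):
                blocks.append((grid.extract(norm, i), grid.extract(lab.labels, i)))
    return blocks


def train_on_blocks(
    net: UNet,
    blocks: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> list[float]:
    """Adam / cross-entropy optimization over shuffled blocks; returns per-step loss."""
    if not blocks:
        raise ValueError("empty training set")
    params, grads = net.parameters()
    opt = Adam(params, grads, lr=cfg.learning_rate, betas=cfg.betas)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    steps = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(len(blocks))
        for i0 in range(0, len(order), cfg.batch_size):
            sel = order[i0 : i0 + cfg.batch_size]
            xs, ts = [], []
            for j in sel:
                img, lab = blocks[j]
                if cfg.augment_elastic and img.ndim == 2:
                    img, lab = _elastic_2d(img, lab, rng)
                xs.append(img)
                ts.append(lab)
            x = np.stack(xs)[:, None].astype(np.float32)
            t = np.stack(ts)
            opt.zero_grad()
            scores = net.forward(x, train=True)
            loss, dscores = cross_entropy(scores, t)
            net.backward(dscores)
            opt.step()
            history.append(loss)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                return history
    return history


def train_fold(
    fold: tuple[list[str], str],
    model_config: UNetConfig,
    cfg: TrainConfig,
    data: dict[str, tuple[OCTVolume, LabelVolume]],
    fold_id: int = 0,
) -> FoldResult:
    """Train one fold and score it on its validation volume."""
    train_ids, val_id = fold
    if not train_ids:
        raise ValueError("empty training set")
    blocks = _training_blocks(data, train_ids, model_config.dims, cfg)
    net = build_unet(model_config)
    history = train_on_blocks(net, blocks, cfg)
    val_vol, val_lab = data[val_id]
    pred = segment_volume(val_vol, net, cfg)
    report = dice(val_lab, pred)
    return FoldResult(
        fold_id=fold_id,
        net=net,
        val_dsc=dict(report.dsc),
        mean_tissue_dsc=report.mean_tissue(),
        loss_history=history,
    )


def segment_volume(
    vol: OCTVolume,
    net: UNet,
    cfg: TrainConfig | None = None,
    stride: tuple[int, int] = (32, 32),
    blend: BlendParams | None = None,
) -> LabelVolume:
    """Segment a full volume with the trained network (slice-wise for 2D,
    Gaussian-blended overlapping blocks for 3D)."""
    cfg = cfg or TrainConfig()
    norm = lambda x: percentile_normalize(x, cfg.norm_percentile)
    if net.config.dims == 2:
        grid = None
    else:
        from .blocks import split_3d_overlap

        shape = cfg.block_shape_3d or (vol.shape[0], 64, 64)
        stride = (min(stride[0], shape[1]), min(stride[1], shape[2]))
        grid = split_3d_overlap(vol, shape, stride)
    return blend_predict(vol, net, grid=grid, params=blend, normalize=norm)


def select_best(folds: list[FoldResult]) -> FoldResult:
    """Fold with the highest mean tissue DSC; ties break to the lowest fold_id."""
    if not folds:
        raise ValueError("no folds to select from")
    return max(sorted(folds, key=lambda f: f.fold_id), key=lambda f: f.mean_tissue_dsc)


def run_cross_validation(
    plan: CVPlan,
    model_config: UNetConfig,
    cfg: TrainConfig,
    data: dict[str, tuple[OCTVolume, LabelVolume]],
    log_path=None,
) -> tuple[list[FoldResult], FoldResult]:
    """Train every fold, log metrics, and return (folds, best fold)."""
    results = []
    for k, fold in enumerate(plan.folds):
        fc = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        results.append(train_fold(fold, model_config, fc, data, fold_id=k))
    best = select_best(results)
    if log_path is not None:
        payload = [
            {
                "fold_id": r.fold_id,
                "val_dsc": r.val_dsc,
                "mean_tissue_dsc": r.mean_tissue_dsc,
                "final_loss": r.loss_history[-1] if r.loss_history else None,
            }
            for r in results
        ]
        with open(log_path, "w") as f:
            json.dump({"folds": payload, "best_fold": best.fold_id}, f, indent=2)
    return results, best
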