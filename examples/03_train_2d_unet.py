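"""Train a small 2D U-Net on phantom B-scans and segment a held-out volume.

Desk-scale version of the full workflow: 6 phantom volumes, 5 for training,
1 held out; width-reduced network; cross-entropy + Adam (lr 0.001,
betas (0.9, 0.98)).  Takes a few minutes on one CPU.
"""

from octskin import (
    PhantomParams,
    TrainConfig,
    desk_geometry,
    make_dataset,
    train_fold,
)
from octskin.nn.unet import UNetConfig

params = PhantomParams(
    geometry=desk_geometry(112, 128, 64), thickness_jitter_frac=0.05, seed=0
)
phantoms = make_dataset(6, params, seed=17)
data = {f"v{i}": (ph.volume, ph.truth) for i, ph in enumerate(phantoms)}

model = UNetConfig(dims=2, width_multiplier=0.25, seed=0)
cfg = TrainConfig(epochs=2, batch_size=4, max_steps=130, seed=0)
result = train_fold((["v0", "v1", "v2", "v3", "v4"], "v5"), model, cfg, data)

print(f"training loss: {result.loss_history[0]:.3f} -> {result.loss_history[-1]:.3f}")
print("held-out per-class DSC:", {k: round(v, 3) for k, v in result.val_dsc.items()})
print(f"mean tissue DSC (classes 2-5): {result.mean_tissue_dsc:.3f}")
# Mean tissue DSC well above 0.87 shows the network segments unseen phantom
# anatomy, not just the training volumes.
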