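# octskin

Segmentation of 3D optical coherence tomography (OCT) images of human thick
skin into five structural classes, with layer-thickness morphometry.

OCT of finger-pad skin resolves, in depth order along every A-scan: the
probe–skin gap, a thin bright **upper stratum corneum**, a thick dimmer
**ordered stratum corneum**, the brighter **cellular epidermis**, and the
dimmer **dermis** (whose lower border lies beyond the probing depth).
Delineating these layers in 256×512×512-voxel volumes by hand is impractical,
and the low boundary contrast — comparable to the speckle contrast — defeats
simple edge detectors.  This package implements a complete pipeline for the
problem, aimed at researchers in biomedical optics and quantitative
dermatology:

* **Semi-automatic statistical labeler** — per-layer thresholds
  `I_t = mean(M_i) − α_i·std(M_i)` from operator-chosen regions `M_i`,
  downward threshold-crossing boundary detection per A-scan, median smoothing
  of the boundary surface (w = 11), and 3D median despeckling below the first
  boundary, iterated over layers 2..5.
* **2D and 3D U-Nets** — five-stage encoder–decoders (32…512 features,
  conv3 → batch norm → ReLU ×2, 2× max-pool, transposed-conv upsampling, skip
  concatenation, 1×1 head) emitting five per-voxel class confidences,
  implemented in pure NumPy with verified analytic gradients and an Adam
  optimizer (lr 0.001, betas (0.9, 0.98)).
* **Block pipelines** — training on B-scan blocks (256×512×1, 256 per volume)
  or disjoint 3D tiles (256×64×64, 32 per volume); 3D inference on
  overlapping blocks with Gaussian-weighted confidence blending
  (σ = 16 voxels) to eliminate tile seams.
* **Leave-one-out cross-validation** — seeded test-set holdout, one fold per
  remaining volume, best fold selected by mean tissue DSC.
* **Evaluation** — per-class Sørensen–Dice coefficients
  `DSC_i = 2|A∩B| / (|A|+|B|)` and per-layer geometric thickness
  `t = N_vox · Δz_opt / n` with refractive index n = 1.4, cohort statistics
  as M ± SD.
* **Speckle phantom generator** — seeded, ground-truthed synthetic volumes
  with the thick-skin contrast ordering, papillary boundary undulation,
  exponential depth attenuation and multiplicative gamma speckle, standing in
  for clinical data in all tests.

See `docs/methods.md` for the underlying models and design choices.

## Worked example

Label a speckled phantom and compare with its ground truth
(`examples/02_semiauto_labeling.py`):

```text
per-class DSC vs ground truth:
  class 1 (background): 1.000
  class 2 (upper_sc  ): 0.903
  class 3 (ordered_sc): 0.978
  class 4 (epidermis ): 0.969
  class 5 (dermis    ): 0.981
boundary of layer 2: median |dz| = 0.0 voxels
boundary of layer 3: median |dz| = 1.0 voxels
boundary of layer 4: median |dz| = 1.0 voxels
boundary of layer 5: median |dz| = 1.0 voxels
```

DSC = 1 would be a perfect voxel match; values near 0.97 for the thick layers
with ≤ 1 voxel median boundary error mean the labeler recovers the planted
anatomy through speckle whose contrast (1/√8 ≈ 0.35) rivals the layer
contrast.  The thin upper stratum corneum scores lower because a one-voxel
boundary shift is a large fraction of its ~5-voxel thickness.

The other scripts in `examples/` demonstrate phantom generation, 2D U-Net
training on phantoms, seamless overlapping-block 3D inference, and cohort
thickness estimation, each printing the quantities it computes.

A command-line interface covers the same workflow end to end:

```sh
octskin phantom --out data/ --n 7 --desk --seed 1
octskin label --volume data/vol_00.tiff --out labels.tiff
octskin train --data data/ --out run/ --model 2d --width 0.25 --max-steps 200
octskin segment --weights run/best.npz --in data/vol_06.tiff --out pred.tiff
octskin evaluate --true data/truth_06.tiff --pred pred.tiff --report dsc.json
octskin thickness --labels data/ --layer ordered_sc --n 1.4 --out thickness.csv
octskin pipeline config.yaml   # all stages from one YAML, with a run manifest
```

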