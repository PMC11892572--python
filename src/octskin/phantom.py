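"""Seeded speckle phantoms of layered thick skin for OCT segmentation.

The generator emulates the contrast sequence seen in finger-pad OCT: a dark
probe gap above the skin, a thin bright upper stratum corneum, a thick dimmer
ordered stratum corneum, a brighter cellular epidermis and a dimmer dermis
that continues past the imaging depth.  Boundaries of the epidermis carry a
sinusoidal papillary undulation; intensity decays exponentially with optical
depth below the tissue surface and is multiplied by unit-mean gamma speckle.

Layer thicknesses are specified geometrically in micrometres and converted to
optical voxel spans via the tissue refractive index (1.4 by default), mirroring
how thicknesses are read back out of segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import (
    BoundarySurface,
    LabelVolume,
    OCTVolume,
    VoxelGeometry,
    labels_from_surfaces,
)

#: Mean layer signal in relative units; ordering I2 > I4 > I3 > I5 > I1 is the
#: thick-skin contrast sequence (bright upper SC, dark ordered SC, brighter
#: epidermis, dimmer dermis, near-dark probe gap).
DEFAULT_INTENSITY = {1: 5.0, 2: 100.0, 3: 40.0, 4: 70.0, 5: 30.0}

#: Mean geometric layer thicknesses in micrometres.  Layers 3 and 4 use the
#: cohort means measured for the ordered stratum corneum (153 um) and the
#: cellular epidermis (137 um); the thin upper stratum corneum is set to 20 um,
#: comparable to the 15 um axial resolution.  The dermis fills the remaining
#: depth (its lower border is beyond the imaging range).
DEFAULT_THICKNESS_UM = {2: 20.0, 3: 153.0, 4: 137.0}


def desk_geometry(n_z: int = 128, n_y: int = 256, n_x: int = 128) -> VoxelGeometry:
    """A reduced grid with the acquisition system's lateral pitch (5.86 um/voxel
    laterally and optically in depth), sized for quick CPU experiments."""
    pitch = 3.0 / 512
    return VoxelGeometry(n_z, n_y, n_x, n_z * pitch, n_y * pitch, n_x * pitch)


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the layered skin phantom."""

    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry(256, 512, 256, 1.2, 3.0, 1.5)
    )
    gap_depth_vox: float = 15.0
    layer_thickness_um: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_THICKNESS_UM)
    )
    thickness_jitter_frac: float = 0.0
    refractive_index: float = 1.4
    layer_mean_intensity: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY)
    )
    attenuation_per_mm: float = 1.0
    undulation_amplitude_vox: float = 3.0
    undulation_period_vox: float = 40.0
    tilt_amplitude_vox: float = 2.0
    speckle_shape: float = 4.0
    speckle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        I = self.layer_mean_intensity
        if not (I[2] > I[4] > I[3] and I[4] > I[5] and I[1] < I[3]):
            raise ValueError(
                "layer intensities must satisfy I2 > I4 > I3, I4 > I5, I1 < I3"
            )
        if any(t <= 0 for t in self.layer_thickness_um.values()):
            raise ValueError("layer thicknesses must be > 0")
        if self.undulation_period_vox <= 0 or self.undulation_amplitude_vox < 0:
            raise ValueError("undulation period must be > 0 and amplitude >= 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        if self.gap_depth_vox < 0:
            raise ValueError("gap_depth_vox must be >= 0")
        if self.total_optical_depth_vox >= self.geometry.n_z:
            raise ValueError(
                "gap depth plus optical layer thicknesses exceed the grid depth"
            )

    def optical_thickness_vox(self, layer: int) -> float:
        """Mean optical span of a layer in voxels: t_um * n / dz_opt."""
        return (
            self.layer_thickness_um[layer]
            * self.refractive_index
            / self.geometry.dz_opt_um
        )

    @property
    def total_optical_depth_vox(self) -> float:
        return self.gap_depth_vox + sum(
            self.optical_thickness_vox(i) for i in (2, 3, 4)
        )


@dataclass
class Phantom:
    """A rendered phantom: intensity volume, truth labels and true boundaries."""

    volume: OCTVolume
    truth: LabelVolume
    boundaries: list[BoundarySurface]
    params: PhantomParams


def _smooth_tilt(rng: np.random.Generator, n_y: int, n_x: int, amp: float) -> np.ndarray:
    """Low-frequency random tilt: a plane with small random slopes."""
    ay, ax = rng.uniform(-amp, amp, size=2)
    yy = np.linspace(-0.5, 0.5, n_y)[:, None]
    xx = np.linspace(-0.5, 0.5, n_x)[None, :]
    return ay * yy + ax * xx


def _undulation(
    rng: np.random.Generator, n_y: int, n_x: int, amp: float, period: float
) -> np.ndarray:
    """Sinusoidal papillary relief with random phases along both lateral axes."""
    phi_y, phi_x = rng.uniform(0, 2 * np.pi, size=2)
    yy = np.arange(n_y)[:, None]
    xx = np.arange(n_x)[None, :]
    return amp * np.sin(2 * np.pi * yy / period + phi_y) * np.sin(
        2 * np.pi * xx / period + phi_x
    )


def sample_boundaries(
    params: PhantomParams, rng: np.random.Generator | None = None
) -> list[BoundarySurface]:
    """Draw the four upper-boundary surfaces z_2 <= z_3 <= z_4 <= z_5.

    Surfaces 2 and 3 are smooth (random tilt only); surfaces 4 and 5 carry the
    sinusoidal papillary undulation.  Consecutive surfaces are separated by the
    layer's optical thickness in expectation, and ordering is enforced by
    clamping each surface below the one above.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    g = params.geometry
    n_y, n_x = g.n_y, g.n_x
    z2 = params.gap_depth_vox + _smooth_tilt(rng, n_y, n_x, params.tilt_amplitude_vox)
    z3 = z2 + params.optical_thickness_vox(2)
    z4 = z3 + params.optical_thickness_vox(3) + _undulation(
        rng, n_y, n_x, params.undulation_amplitude_vox, params.undulation_period_vox
    )
    z5 = z4 + params.optical_thickness_vox(4) + _undulation(
        rng, n_y, n_x, params.undulation_amplitude_vox, params.undulation_period_vox
    )
    surfaces = []
    prev = np.zeros((n_y, n_x))
    for layer, z in zip((2, 3, 4, 5), (z2, z3, z4, z5)):
        z = np.maximum(z, prev)
        if z.max() >= g.n_z:
            raise ValueError(
                f"surface {layer} reaches past the grid bottom (max z={z.max():.1f})"
            )
        surfaces.append(BoundarySurface(layer, z))
        prev = z
    return surfaces


def render_phantom(params: PhantomParams) -> Phantom:
    """Render a phantom volume with its ground truth.

    The noise-free image is the per-class mean intensity attenuated as
    exp(-mu * optical depth below the tissue surface); speckle multiplies it by
    i.i.d. unit-mean gamma noise.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    g = params.geometry
    surfaces = sample_boundaries(params, rng)
    truth = labels_from_surfaces(surfaces, g)

    means = np.zeros(6, dtype=np.float64)
    for cls, v in params.layer_mean_intensity.items():
        means[cls] = v
    img = means[truth.labels]

    # attenuation measured from the tissue surface (top of class 2), in mm of
    # optical path; the probe gap is not attenuated
    z_surf = surfaces[0].rounded()[None, :, :]
    depth_vox = np.arange(g.n_z)[:, None, None] - z_surf
    depth_mm = np.clip(depth_vox, 0, None) * g.dz_opt_mm
    img = img * np.exp(-params.attenuation_per_mm * depth_mm)

    if params.speckle:
        k = params.speckle_shape
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)

    vol = OCTVolume(img.astype(np.float32), g, identifier=f"phantom-{params.seed}")
    return Phantom(vol, truth, surfaces, params)


def make_dataset(
    n_volumes: int, params: PhantomParams, seed: int | None = None
) -> list[Phantom]:
    """Generate a reproducible cohort of phantoms with jittered thicknesses.

    Each volume gets an independent sub-seed derived from ``seed`` (defaulting
    to ``params.seed``) and a per-volume thickness draw with relative SD
    ``thickness_jitter_frac``.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    root = params.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    phantoms = []
    for i, child in enumerate(ss.spawn(n_volumes)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        thick = dict(params.layer_thickness_um)
        if params.thickness_jitter_frac > 0:
            for layer in thick:
                draw = rng.normal(thick[layer], params.thickness_jitter_frac * thick[layer])
                thick[layer] = max(draw, 0.1 * thick[layer])
        p = replace(params, layer_thickness_um=thick, seed=sub_seed)
        ph = render_phantom(p)
        ph.volume.identifier = f"phantom-{i:02d}"
        ph.truth.identifier = f"phantom-{i:02d}"
        phantoms.append(ph)
    return phantoms
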