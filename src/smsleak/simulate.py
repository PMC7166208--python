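"""Synthetic 4D SMS-EPI series with block-locked slice leakage.

The simulator emulates the forceful-blinking experiment: an ellipsoidal
head phantom carries an anterior "eye" source disk whose signal jumps
volume-to-volume during task-on blocks, and scaled copies of that
fluctuation are deposited at every geometrically predicted alias position
(inter-slice CAIPI copies and, with GRAPPA acceleration, FOV/2 ghosts).
The injected masks are returned as ground truth, making the simulator an
oracle for both the alias predictor and the quantification statistic.

The per-volume source fluctuation is an independent zero-mean Gaussian
draw during on blocks (abrupt, blink-locked signal change rather than a
smooth haemodynamic response, since the statistic measures volume-to-
volume change); its sign varies, so leakage contains both bright and dark
voxels.  Leakage is deposited with a Gaussian radial profile peaked at
the disk center, a point-spread-like falloff that makes variance-map
local maxima coincide with the injected centers.  Additive noise is
Gaussian, adequate at high SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import AcquisitionGeometry, AliasKind, VoxelCoord
from .metrics import BlockDesign, blinking_paradigm
from .regions import AliasLocation, RegionMask, alias_label, disk_mask, predict_alias_locations

__all__ = [
    "SimulationScenario",
    "SimulationResult",
    "default_geometry",
    "reduced_geometry",
    "default_scenario",
    "reduced_scenario",
    "head_phantom",
    "simulate",
]

ALIAS_DISK_DIAMETER = 7


def default_geometry() -> AcquisitionGeometry:
    """The reference SMS-EPI protocol: 96x96x68 grid of 2 mm voxels
    (192 mm in-plane FOV), MB4, GRAPPA 2, FOV/3 CAIPI shift,
    anterior-posterior phase encoding, TR 1.5 s."""
    return AcquisitionGeometry(
        nx=96,
        ny=96,
        nz=68,
        voxel_size=(2.0, 2.0, 2.0),
        mb_factor=4,
        grappa_factor=2,
        caipi_denominator=3,
        pe_axis="y",
        tr=1.5,
    )


def reduced_geometry() -> AcquisitionGeometry:
    """A desk-scale variant of the reference protocol: 48x48x16 grid of
    4 mm voxels (same 192 mm FOV), identical acceleration parameters."""
    return AcquisitionGeometry(
        nx=48,
        ny=48,
        nz=16,
        voxel_size=(4.0, 4.0, 4.0),
        mb_factor=4,
        grappa_factor=2,
        caipi_denominator=3,
        pe_axis="y",
        tr=1.5,
    )


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic blinking run.

    Intensities are in arbitrary scanner units.  ``source_amplitude`` is
    the standard deviation of the per-volume source fluctuation during on
    blocks; ``leak_fraction_*`` are the fractions of that fluctuation
    copied to each alias disk; ``noise_sd`` is the additive Gaussian noise
    level (the default is 2% of the default source amplitude).
    """

    geom: AcquisitionGeometry
    design: BlockDesign
    source_center: VoxelCoord
    source_radius: int = 3
    baseline_brain: float = 1000.0
    baseline_background: float = 0.0
    source_amplitude: float = 100.0
    leak_fraction_caipi: float = 0.2
    leak_fraction_grappa: float = 0.2
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("leak_fraction_caipi", "leak_fraction_grappa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.source_amplitude < 0:
            raise ParameterError("source_amplitude must be >= 0")
        if self.source_radius < 0:
            raise ParameterError("source_radius must be >= 0")
        c, r = VoxelCoord(*self.source_center), self.source_radius
        g = self.geom
        if not (r <= c.x < g.nx - r and r <= c.y < g.ny - r and 0 <= c.z < g.nz):
            raise ParameterError(
                f"source disk (center {tuple(c)}, radius {r}) must lie "
                f"inside the {g.nx}x{g.ny}x{g.nz} grid"
            )


def default_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Reference-protocol scenario: eye source at voxel (32, 91, 18),
    7.5 cycles of 20 s blinking / 20 s rest (200 volumes)."""
    geom = overrides.pop("geom", default_geometry())
    params = dict(
        geom=geom,
        design=blinking_paradigm(tr=geom.tr),
        source_center=VoxelCoord(32, 91, 18),
        seed=seed,
    )
    params.update(overrides)
    return SimulationScenario(**params)


def reduced_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Desk-scale scenario on the 48x48x16 grid with the eye source moved
    to the anterior midline (24, 45, 9)."""
    geom = overrides.pop("geom", reduced_geometry())
    params = dict(
        geom=geom,
        design=blinking_paradigm(tr=geom.tr),
        source_center=VoxelCoord(24, 45, 9),
        source_radius=2,
        seed=seed,
    )
    params.update(overrides)
    return SimulationScenario(**params)


@dataclass
class SimulationResult:
    """A simulated run plus its injection ground truth."""

    data: np.ndarray  # (nx, ny, nz, T) float32
    geom: AcquisitionGeometry
    design: BlockDesign
    scenario: SimulationScenario
    source_mask: RegionMask
    alias_locations: list[AliasLocation]
    alias_masks: list[RegionMask]
    brain_mask: np.ndarray  # ellipsoid head, bool
    head_mask: np.ndarray  # ellipsoid plus the eye disk, bool
    source_fluctuation: np.ndarray  # f(t), length T


# Head semi-axes as fractions of the grid extent per axis.  The phantom is
# deliberately narrower left-right than anterior-posterior, like a head in
# a lateral-FOV prescription, so that switching the phase-encode axis to
# left-right pushes aliases of an anterior source out of the head.
_HEAD_SEMIAXES = (0.35, 0.46, 0.48)


def head_phantom(geom: AcquisitionGeometry) -> np.ndarray:
    """Ellipsoidal head mask centered on the grid (bool array)."""
    nx, ny, nz = geom.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = (f * n for f, n in zip(_HEAD_SEMIAXES, (nx, ny, nz)))
    x = (np.arange(nx)[:, None, None] - cx) / rx
    y = (np.arange(ny)[None, :, None] - cy) / ry
    z = (np.arange(nz)[None, None, :] - cz) / rz
    return x * x + y * y + z * z <= 1.0


def _disk_weights(mask: RegionMask, sigma: float) -> np.ndarray:
    """Gaussian radial profile over a disk's voxels, 1 at the center."""
    xs, ys, _ = mask.indices()
    r2 = (xs - mask.center.x) ** 2 + (ys - mask.center.y) ** 2
    return np.exp(-r2 / (2.0 * sigma * sigma))


def simulate(scenario: SimulationScenario) -> SimulationResult:
    """Generate one synthetic 4D run; deterministic given the scenario seed.

    Draw order is fixed (source fluctuation first, then noise) so a seed
    fully determines the output.
    """
    geom = scenario.geom
    design = scenario.design
    T = design.n_volumes
    rng = np.random.default_rng(scenario.seed)

    source_mask = disk_mask(
        VoxelCoord(*scenario.source_center),
        2 * scenario.source_radius + 1,
        geom,
        label="source",
    )
    brain = head_phantom(geom)
    head = brain.copy()
    sx, sy, sz = source_mask.indices()
    head[sx, sy, sz] = True

    base = np.where(head, scenario.baseline_brain, scenario.baseline_background)
    data = np.empty(geom.shape + (T,), dtype=np.float32)
    data[...] = base[..., None]

    on_vols = np.array([lab == "on" for lab in design.volume_labels()])
    f = np.zeros(T)
    f[on_vols] = rng.normal(0.0, scenario.source_amplitude, size=int(on_vols.sum()))

    def deposit(mask: RegionMask, amplitude_fraction: float, radius: int) -> None:
        xs, ys, zs = mask.indices()
        w = _disk_weights(mask, sigma=max(radius, 1) / 2.0)
        data[xs, ys, zs, :] += (
            amplitude_fraction * w[:, None] * f[None, :]
        ).astype(np.float32)

    deposit(source_mask, 1.0, scenario.source_radius)

    alias_locations = predict_alias_locations(VoxelCoord(*scenario.source_center), geom)
    alias_masks = []
    for loc in alias_locations:
        frac = (
            scenario.leak_fraction_caipi
            if loc.kind is AliasKind.CAIPI
            else scenario.leak_fraction_grappa
        )
        mask = disk_mask(loc.coord, ALIAS_DISK_DIAMETER, geom, label=alias_label(loc))
        deposit(mask, frac, ALIAS_DISK_DIAMETER // 2)
        alias_masks.append(mask)

    if scenario.noise_sd > 0:
        noise = rng.standard_normal(size=data.shape, dtype=np.float32)
        noise *= scenario.noise_sd
        data += noise

    return SimulationResult(
        data=data,
        geom=geom,
        design=design,
        scenario=scenario,
        source_mask=source_mask,
        alias_locations=alias_locations,
        alias_masks=alias_masks,
        brain_mask=brain,
        head_mask=head,
        source_fluctuation=f,
    )
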