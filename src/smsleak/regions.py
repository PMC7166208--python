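"""Alias-location prediction and disk-shaped region masks.

For a given source voxel (typically the eye), every simultaneously excited
slice is expected to receive aliased copies of the source signal: one at
the CAIPI FOV/k shift and, when in-plane GRAPPA acceleration is used, one
a further FOV/2 along the phase-encode axis.  Around each predicted
position (and at control positions) a small in-plane disk mask is built
for quantification; a diameter-7 disk on the acquisition lattice contains
29 voxels.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, PlacementError
from .geometry import (
    AcquisitionGeometry,
    AliasKind,
    VoxelCoord,
    pe_shift_voxels,
    slice_group,
)

__all__ = [
    "AliasLocation",
    "RegionMask",
    "predict_alias_locations",
    "disk_mask",
    "control_masks",
    "alias_label",
]


@dataclass(frozen=True)
class AliasLocation:
    """One predicted artefact position.

    ``m`` is the slice-offset index 1..M in cyclic ascending slice order
    starting at the first simultaneous slice after the source slice, so
    m = M is the source slice itself (the intra-slice alias).  A location
    that lands exactly on the source voxel is flagged, not dropped.
    """

    coord: VoxelCoord
    slice_index: int
    kind: AliasKind
    m: int
    is_source_coincident: bool = False

    def __post_init__(self) -> None:
        if self.coord.z != self.slice_index:
            raise ParameterError("alias coordinate must lie in its slice")


@dataclass(frozen=True)
class RegionMask:
    """A labelled set of in-plane voxels sharing one slice."""

    label: str
    center: VoxelCoord
    voxels: frozenset[VoxelCoord]

    def __post_init__(self) -> None:
        if any(v.z != self.center.z for v in self.voxels):
            raise ParameterError(
                f"mask {self.label!r}: all member voxels must share the "
                "center's slice (in-plane mask)"
            )

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Member voxels as index arrays suitable for numpy fancy indexing."""
        vox = sorted(self.voxels)
        xs = np.array([v.x for v in vox], dtype=np.intp)
        ys = np.array([v.y for v in vox], dtype=np.intp)
        zs = np.array([v.z for v in vox], dtype=np.intp)
        return xs, ys, zs


def alias_label(loc: AliasLocation) -> str:
    """Figure-style label: A, B, C, ... for CAIPI; Ag, Bg, ... for GRAPPA."""
    letter = string.ascii_uppercase[(loc.m - 1) % 26]
    return letter + ("g" if loc.kind is AliasKind.GRAPPA else "")


def predict_alias_locations(
    source: VoxelCoord, geom: AcquisitionGeometry
) -> list[AliasLocation]:
    """Predict every expected alias position for a signal source.

    Within each of the M simultaneously excited slices one CAIPI alias is
    expected at the source phase-encode coordinate plus (FOV/k)*m mod FOV,
    and, when the GRAPPA factor R > 1, one further alias FOV/2 along.
    Slices are taken in cyclic ascending order starting after the source
    slice and indexed m = 1..M; the non-phase-encode in-plane coordinate
    is unchanged.  Returns 2M locations when R > 1, M otherwise.

    Examples
    --------
    >>> g = AcquisitionGeometry(96, 96, 68, mb_factor=4, grappa_factor=2)
    >>> locs = predict_alias_locations(VoxelCoord(32, 91, 18), g)
    >>> len(locs)
    8
    """
    source = VoxelCoord(*source)
    geom.require_inside(source)
    group = slice_group(geom, source.z)
    pivot = group.index(source.z)
    ordered = group[pivot + 1:] + group[: pivot + 1]

    src_pe = source.x if geom.pe_axis == "x" else source.y
    kinds = [AliasKind.CAIPI]
    if geom.grappa_factor > 1:
        kinds.append(AliasKind.GRAPPA)

    locations: list[AliasLocation] = []
    for m, z in enumerate(ordered, start=1):
        for kind in kinds:
            pe = (src_pe + pe_shift_voxels(geom, kind, m)) % geom.n_pe
            if geom.pe_axis == "x":
                coord = VoxelCoord(pe, source.y, z)
            else:
                coord = VoxelCoord(source.x, pe, z)
            locations.append(
                AliasLocation(
                    coord=coord,
                    slice_index=z,
                    kind=kind,
                    m=m,
                    is_source_coincident=coord == source,
                )
            )
    return locations


def disk_mask(
    center: VoxelCoord,
    diameter: int,
    geom: AcquisitionGeometry,
    label: str | None = None,
) -> RegionMask:
    """In-plane Euclidean lattice disk of odd ``diameter`` about ``center``.

    Includes integer offsets with dx^2 + dy^2 <= floor(diameter/2)^2, the
    rasterisation for which a diameter-7 disk contains exactly 29 voxels
    (and a diameter-5 disk 13).  Disks abutting the grid edge are clipped
    with a warning rather than rejected.
    """
    if diameter < 1 or diameter % 2 == 0:
        raise ParameterError(f"disk diameter must be odd and >= 1, got {diameter}")
    center = VoxelCoord(*center)
    geom.require_inside(center)
    r = diameter // 2
    voxels = set()
    clipped = False
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            if dx * dx + dy * dy > r * r:
                continue
            v = VoxelCoord(center.x + dx, center.y + dy, center.z)
            if geom.contains(v):
                voxels.add(v)
            else:
                clipped = True
    if clipped:
        warnings.warn(
            f"disk at {tuple(center)} clipped at the grid edge; "
            f"{len(voxels)} voxels remain",
            stacklevel=2,
        )
    return RegionMask(
        label=label if label is not None else f"disk@{tuple(center)}",
        center=center,
        voxels=frozenset(voxels),
    )


def control_masks(
    geom: AcquisitionGeometry,
    alias_locs: list[AliasLocation],
    brain: np.ndarray,
    n: int = 2,
    min_distance: float = 10.0,
    seed: int = 0,
    diameter: int = 7,
) -> list[RegionMask]:
    """Place ``n`` control disks inside the brain, away from alias positions.

    Control centers are drawn uniformly (seeded) from brain voxels at
    Euclidean distance >= ``min_distance`` from every predicted alias
    center; chosen controls are additionally kept at least one mask
    diameter apart from each other so they never overlap.
    """
    if n < 1:
        raise ParameterError("at least one control region must be requested")
    brain = np.asarray(brain, dtype=bool)
    if brain.shape != geom.shape:
        raise ParameterError(
            f"brain mask shape {brain.shape} does not match grid {geom.shape}"
        )
    cand = np.argwhere(brain).astype(float)  # (K, 3) rows of (x, y, z)
    if cand.size == 0:
        raise PlacementError("brain mask is empty; no feasible control centers")
    if alias_locs:
        centers = np.array([tuple(loc.coord) for loc in alias_locs], dtype=float)
        d2 = ((cand[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        feasible = cand[(d2 >= min_distance**2).all(axis=1)]
    else:
        feasible = cand
    if len(feasible) == 0:
        raise PlacementError(
            f"no brain voxel is >= {min_distance} voxels from every alias "
            "center; relax min_distance or enlarge the brain mask"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(feasible))
    chosen: list[VoxelCoord] = []
    for idx in order:
        c = VoxelCoord(*feasible[idx].astype(int))
        if all(
            (c.x - p.x) ** 2 + (c.y - p.y) ** 2 + (c.z - p.z) ** 2 >= diameter**2
            for p in chosen
        ):
            chosen.append(c)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise PlacementError(
            f"could not place {n} non-overlapping control disks "
            f"(found {len(chosen)}) under min_distance={min_distance}"
        )
    return [
        disk_mask(c, diameter, geom, label=f"control_{i + 1}")
        for i, c in enumerate(chosen)
    ]
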