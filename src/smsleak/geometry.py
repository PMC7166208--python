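"""Acquisition geometry for simultaneous multi-slice (SMS/multiband) EPI.

The geometry object captures everything the alias arithmetic depends on:
the in-plane matrix, the slice count, the multiband factor M (number of
simultaneously excited slices), the in-plane GRAPPA acceleration factor R,
the CAIPIRINHA inter-slice field-of-view shift (FOV/k, k = 3 for the
standard SMS-EPI protocol) and the phase-encode axis.  Aliasing wraps
modulo the FOV along the phase-encode axis, so every shift is expressed in
voxels modulo ``n_pe``, the matrix size along that axis.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import NamedTuple

from .errors import ConfigurationError, CoordinateError, GeometryError, ParameterError

__all__ = [
    "AcquisitionGeometry",
    "AliasKind",
    "VoxelCoord",
    "slice_group",
    "pe_shift_voxels",
]


class VoxelCoord(NamedTuple):
    """A 0-based voxel index triple, x fastest-varying (NIfTI convention)."""

    x: int
    y: int
    z: int


class AliasKind(str, enum.Enum):
    """Alias class: inter-slice CAIPI FOV-shift or in-plane GRAPPA ghost."""

    CAIPI = "caipi"
    GRAPPA = "grappa"


@dataclass(frozen=True)
class AcquisitionGeometry:
    """SMS-EPI acquisition grid and acceleration parameters.

    Parameters
    ----------
    nx, ny :
        In-plane matrix size in voxels.
    nz :
        Number of slices; must be divisible by ``mb_factor``.
    voxel_size :
        Voxel edge lengths in mm, (x, y, z).
    mb_factor :
        Multiband factor M, the number of simultaneously excited slices.
    grappa_factor :
        In-plane GRAPPA acceleration factor R; R > 1 adds an FOV/2 ghost.
    caipi_denominator :
        k such that the inter-slice CAIPI shift is FOV/k (default 3).
    pe_axis :
        Phase-encode axis: ``"y"`` for P>>A / A>>P encoding, ``"x"`` for
        R>>L / L>>R.  Polarity does not move alias positions (aliasing is
        modulo-FOV and sign-free), so both polarities map to one axis.
    tr :
        Repetition time in seconds.
    """

    nx: int
    ny: int
    nz: int
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mb_factor: int = 1
    grappa_factor: int = 1
    caipi_denominator: int = 3
    pe_axis: str = "y"
    tr: float = 1.5

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(
                f"voxel_size must be three positive lengths in mm, got {self.voxel_size}"
            )
        if self.mb_factor < 1:
            raise ConfigurationError("mb_factor must be >= 1")
        if self.grappa_factor < 1:
            raise ConfigurationError("grappa_factor must be >= 1")
        if self.caipi_denominator < 1:
            raise ConfigurationError("caipi_denominator must be >= 1")
        if self.pe_axis not in ("x", "y"):
            raise ConfigurationError(
                f"pe_axis must be 'x' or 'y', got {self.pe_axis!r}"
            )
        if self.nz % self.mb_factor != 0:
            raise ConfigurationError(
                f"number of slices nz={self.nz} is not divisible by "
                f"mb_factor M={self.mb_factor}; slices cannot partition into "
                "simultaneous groups"
            )
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive (seconds)")

    # -- derived quantities -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_pe(self) -> int:
        """Matrix size along the phase-encode axis."""
        return self.nx if self.pe_axis == "x" else self.ny

    @property
    def fov_pe(self) -> float:
        """Field of view along the phase-encode axis, mm."""
        idx = 0 if self.pe_axis == "x" else 1
        return self.n_pe * self.voxel_size[idx]

    @property
    def slice_stride(self) -> int:
        """Distance in slices between members of one simultaneous group."""
        return self.nz // self.mb_factor

    @property
    def caipi_shift_voxels(self) -> int:
        """The unit CAIPI shift FOV/k in voxels, rounded to the lattice.

        Matrices not divisible by the CAIPI denominator are allowed: the
        shift is rounded to the nearest voxel with a warning, since the
        approximation error is at most half a voxel.
        """
        exact = self.n_pe / self.caipi_denominator
        rounded = round(exact)
        if abs(exact - rounded) > 1e-9:
            warnings.warn(
                f"CAIPI shift FOV/{self.caipi_denominator} = {exact:.3f} voxels "
                f"is not integral; rounding to {rounded}",
                stacklevel=2,
            )
        return int(rounded)

    @property
    def grappa_shift_voxels(self) -> int:
        """The GRAPPA ghost offset FOV/2 in voxels (requires even matrix)."""
        if self.n_pe % 2 != 0:
            raise GeometryError(
                f"GRAPPA FOV/2 ghost shift requires an even phase-encode "
                f"matrix; n_pe={self.n_pe}"
            )
        return self.n_pe // 2

    # -- helpers ------------------------------------------------------------

    def contains(self, coord: VoxelCoord) -> bool:
        return (
            0 <= coord.x < self.nx
            and 0 <= coord.y < self.ny
            and 0 <= coord.z < self.nz
        )

    def require_inside(self, coord: VoxelCoord) -> None:
        if not self.contains(coord):
            raise CoordinateError(
                f"voxel {tuple(coord)} lies outside the "
                f"{self.nx}x{self.ny}x{self.nz} grid"
            )


def slice_group(geom: AcquisitionGeometry, z: int) -> list[int]:
    """Return the slices excited simultaneously with slice ``z``, ascending.

    With multiband factor M and nz slices, the nz/M simultaneous groups
    follow the contiguous-stride convention (standard Siemens SMS ordering):
    group members are ``z mod g, z mod g + g, ...`` with stride g = nz/M.

    Examples
    --------
    >>> g = AcquisitionGeometry(96, 96, 68, mb_factor=4)
    >>> slice_group(g, 18)
    [1, 18, 35, 52]
    """
    if not 0 <= z < geom.nz:
        raise CoordinateError(f"slice index {z} outside [0, {geom.nz})")
    g = geom.slice_stride
    base = z % g
    return [base + i * g for i in range(geom.mb_factor)]


def pe_shift_voxels(geom: AcquisitionGeometry, kind: AliasKind, m: int) -> int:
    """Phase-encode shift in voxels for alias class ``kind`` at slice offset ``m``.

    The CAIPI alias for the m-th simultaneous slice sits at
    ``(FOV/k)*m mod FOV``; with in-plane GRAPPA acceleration an additional
    ghost appears a further FOV/2 along, at ``(FOV/k)*m + FOV/2 mod FOV``.
    The result is in voxels, in ``[0, n_pe)``.
    """
    kind = AliasKind(kind)
    if not 1 <= m <= geom.mb_factor:
        raise ParameterError(
            f"slice-offset index m={m} outside 1..M (M={geom.mb_factor})"
        )
    shift = geom.caipi_shift_voxels * m
    if kind is AliasKind.GRAPPA:
        shift += geom.grappa_shift_voxels
    return shift % geom.n_pe
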