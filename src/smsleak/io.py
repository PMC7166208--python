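"""File handling: NIfTI series, label-mask volumes, designs, configs, reports.

All spatial reasoning is in voxel space on the acquisition grid; affines
are passed through unmodified.  CSV outputs carry a single leading '#'
provenance comment line (version, seed, geometry) and use '.' decimals,
comma separators and 6-significant-digit floats so repeated runs are
byte-identical.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InputError
from .geometry import AcquisitionGeometry, VoxelCoord
from .metrics import BlockDesign, Condition
from .regions import RegionMask

__all__ = [
    "SeriesData",
    "read_series",
    "write_series",
    "write_label_masks",
    "read_label_masks",
    "read_config",
    "geometry_from_config",
    "read_design_csv",
    "write_design_csv",
    "write_report_csv",
    "provenance_line",
]


@dataclass
class SeriesData:
    """A 4D series with its grid metadata."""

    data: np.ndarray  # (nx, ny, nz, T)
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def read_series(path: str | Path, geom: AcquisitionGeometry | None = None) -> SeriesData:
    """Load a 4D NIfTI time series, optionally validating against a geometry."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / not NIfTI
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 4:
        raise InputError(f"{path}: expected a 4D series, got {img.ndim} dimensions")
    data = np.asarray(img.get_fdata(dtype=np.float32))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if geom is not None:
        if data.shape[:3] != geom.shape:
            raise InputError(
                f"{path}: grid {data.shape[:3]} does not match configured "
                f"geometry {geom.shape}"
            )
        if not np.allclose(zooms, geom.voxel_size, atol=1e-3):
            raise InputError(
                f"{path}: header voxel size {zooms} mm does not match "
                f"configured {geom.voxel_size} mm"
            )
    return SeriesData(data=data, voxel_size=zooms, affine=img.affine)


def write_series(
    data: np.ndarray,
    voxel_size: tuple[float, float, float],
    path: str | Path,
    tr: float | None = None,
    affine: np.ndarray | None = None,
    descrip: str = "",
) -> None:
    """Write a 3D or 4D array as NIfTI-1 with the given voxel sizes."""
    if affine is None:
        affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(voxel_size) + ([tr] if (tr and data.ndim == 4) else [])
    img.header.set_zooms(tuple(zooms) + (1.0,) * (data.ndim - len(zooms)))
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def _sidecar_path(path: str | Path) -> Path:
    path = str(path)
    return Path(re.sub(r"\.nii(\.gz)?$", "", path) + ".csv")


def write_label_masks(
    masks: list[RegionMask],
    geom: AcquisitionGeometry,
    path: str | Path,
    seed: int | None = None,
) -> Path:
    """Write region masks as an integer label volume plus a sidecar CSV.

    Label i+1 marks region i; 0 is background.  Overlapping voxels keep
    the first region's label (first-wins) with a warning.  Returns the
    sidecar path; the sidecar maps label values to region metadata and
    round-trips losslessly through :func:`read_label_masks` for
    non-overlapping masks.
    """
    vol = np.zeros(geom.shape, dtype=np.int16)
    for i, mask in enumerate(masks, start=1):
        xs, ys, zs = mask.indices()
        taken = vol[xs, ys, zs] != 0
        if taken.any():
            warnings.warn(
                f"mask {mask.label!r} overlaps an earlier region on "
                f"{int(taken.sum())} voxel(s); first label wins",
                stacklevel=2,
            )
        keep = ~taken
        vol[xs[keep], ys[keep], zs[keep]] = i
    write_series(vol, geom.voxel_size, path, descrip=provenance_line(geom, seed))
    rows = [
        {
            "value": i,
            "label": m.label,
            "center_x": m.center.x,
            "center_y": m.center.y,
            "center_z": m.center.z,
            "n_voxels": m.n_voxels,
        }
        for i, m in enumerate(masks, start=1)
    ]
    sidecar = _sidecar_path(path)
    write_report_csv(
        pd.DataFrame(rows, columns=["value", "label", "center_x", "center_y", "center_z", "n_voxels"]),
        sidecar,
        geom=geom,
        seed=seed,
    )
    return sidecar


def read_label_masks(path: str | Path) -> list[RegionMask]:
    """Re-read a label volume (with optional sidecar CSV) into region masks."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise InputError(f"{path}: label volume must be 3D, got {img.ndim}D")
    vol = np.asarray(img.dataobj).astype(int)
    labels: dict[int, str] = {}
    centers: dict[int, VoxelCoord] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        tab = pd.read_csv(sidecar, comment="#")
        for _, row in tab.iterrows():
            labels[int(row["value"])] = str(row["label"])
            centers[int(row["value"])] = VoxelCoord(
                int(row["center_x"]), int(row["center_y"]), int(row["center_z"])
            )
    masks = []
    for value in sorted(np.unique(vol[vol > 0])):
        coords = [VoxelCoord(*map(int, idx)) for idx in np.argwhere(vol == value)]
        center = centers.get(value)
        if center is None:
            arr = np.array(coords)
            center = VoxelCoord(*map(int, np.round(arr.mean(axis=0))))
        masks.append(
            RegionMask(
                label=labels.get(value, f"region_{value}"),
                center=center,
                voxels=frozenset(coords),
            )
        )
    return masks


def read_config(path: str | Path) -> dict:
    """Read a flat configuration file: YAML mappings or key=value lines."""
    text = Path(path).read_text()
    # Normalise key=value lines to YAML so one parser handles both styles.
    lines = []
    for line in text.splitlines():
        stripped = line.split("#", 1)[0].rstrip()
        if "=" in stripped and ":" not in stripped:
            key, _, val = stripped.partition("=")
            lines.append(f"{key.strip()}: {val.strip()}")
        else:
            lines.append(line)
    try:
        cfg = yaml.safe_load("\n".join(lines))
    except yaml.YAMLError as exc:
        raise InputError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} must be a flat mapping of keys to values")
    return cfg


_GEOM_KEYS = {
    "nx": ("nx", int),
    "ny": ("ny", int),
    "nz": ("nz", int),
    "mb_factor": ("mb_factor", int),
    "grappa_factor": ("grappa_factor", int),
    "caipi_denominator": ("caipi_denominator", int),
    "pe_axis": ("pe_axis", str),
    "tr_s": ("tr", float),
    "tr": ("tr", float),
}


def geometry_from_config(cfg: dict) -> AcquisitionGeometry:
    """Build an :class:`AcquisitionGeometry` from config keys.

    Recognised keys: nx, ny, nz, voxel_size_mm (scalar or 3-list),
    mb_factor, grappa_factor, caipi_denominator, pe_axis, tr_s.
    """
    kwargs = {}
    for key, (attr, cast) in _GEOM_KEYS.items():
        if key in cfg:
            kwargs[attr] = cast(cfg[key])
    if "voxel_size_mm" in cfg:
        v = cfg["voxel_size_mm"]
        if isinstance(v, (int, float)):
            kwargs["voxel_size"] = (float(v),) * 3
        else:
            vals = [float(x) for x in (v.split(",") if isinstance(v, str) else v)]
            if len(vals) == 1:
                vals = vals * 3
            if len(vals) != 3:
                raise InputError(f"voxel_size_mm must have 1 or 3 entries, got {v!r}")
            kwargs["voxel_size"] = tuple(vals)
    missing = {"nx", "ny", "nz"} - kwargs.keys()
    if missing:
        raise InputError(f"geometry config is missing keys: {sorted(missing)}")
    return AcquisitionGeometry(**kwargs)


def read_design_csv(path: str | Path, tr: float, n_volumes: int) -> BlockDesign:
    """Read a block design from CSV with columns label, onset_s, duration_s."""
    tab = pd.read_csv(path, comment="#")
    required = {"label", "onset_s", "duration_s"}
    if not required <= set(tab.columns):
        raise InputError(
            f"design file {path} must have columns {sorted(required)}, "
            f"got {list(tab.columns)}"
        )
    conditions = tuple(
        Condition(str(r["label"]), float(r["onset_s"]), float(r["duration_s"]))
        for _, r in tab.iterrows()
    )
    return BlockDesign(tr=tr, n_volumes=n_volumes, conditions=conditions)


def write_design_csv(design: BlockDesign, path: str | Path) -> None:
    rows = [
        {"label": c.label, "onset_s": c.onset_s, "duration_s": c.duration_s}
        for c in design.conditions
    ]
    write_report_csv(pd.DataFrame(rows, columns=["label", "onset_s", "duration_s"]), path)


def provenance_line(
    geom: AcquisitionGeometry | None = None, seed: int | None = None
) -> str:
    parts = [f"smsleak v{__version__}"]
    if geom is not None:
        parts.append(
            f"grid={geom.nx}x{geom.ny}x{geom.nz} voxel={geom.voxel_size}mm "
            f"MB={geom.mb_factor} R={geom.grappa_factor} "
            f"CAIPI=FOV/{geom.caipi_denominator} pe_axis={geom.pe_axis} "
            f"TR={geom.tr}s"
        )
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def write_report_csv(
    df: pd.DataFrame,
    path: str | Path,
    geom: AcquisitionGeometry | None = None,
    seed: int | None = None,
) -> None:
    """Write a table as CSV with a '#' provenance header comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {provenance_line(geom, seed)}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
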