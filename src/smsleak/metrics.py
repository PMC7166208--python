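"""Artefact quantification: variance maps and the block-wise
volume-to-volume percentage-signal-change statistic.

The statistic normalises each voxel's consecutive-volume signal change by
that voxel's maximum absolute change over the entire time series, giving a
percentage in [-100, 100].  The mean absolute percentage change is then
computed separately for task-on and task-off blocks over all voxels of a
region mask, and the artefact intensity is the on-minus-off difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError, ParameterError
from .regions import RegionMask

__all__ = [
    "Condition",
    "BlockDesign",
    "IntensityReport",
    "blinking_paradigm",
    "variance_map",
    "percent_signal_change",
    "artefact_intensity",
    "region_report",
    "aggregate_reports",
]


@dataclass(frozen=True)
class Condition:
    label: str
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class BlockDesign:
    """On/off condition timing mapped onto volume indices.

    A volume is assigned to a condition when its midpoint acquisition time
    (t + 0.5)*TR falls inside the condition's [onset, onset + duration)
    interval; midpoint assignment gives unbiased rounding when block
    lengths are not integer multiples of TR (a 20 s block at TR 1.5 s is
    13 1/3 volumes).  Volumes covered by no condition are unlabelled.
    """

    tr: float
    n_volumes: int
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError("tr must be positive")
        if self.n_volumes < 1:
            raise ParameterError("n_volumes must be >= 1")
        conds = tuple(
            c if isinstance(c, Condition) else Condition(*c) for c in self.conditions
        )
        object.__setattr__(self, "conditions", conds)
        ivals = sorted((c.onset_s, c.onset_s + c.duration_s) for c in conds)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1 - 1e-9:
                raise ParameterError(
                    f"condition intervals overlap: [{a0}, {a1}) and [{b0}, {b1})"
                )
        total = self.n_volumes * self.tr
        if ivals and ivals[-1][1] > total + 1e-9:
            raise ParameterError(
                f"conditions extend to {ivals[-1][1]:g} s but the series "
                f"covers only {total:g} s ({self.n_volumes} volumes x "
                f"{self.tr:g} s)"
            )

    @property
    def total_duration_s(self) -> float:
        return self.n_volumes * self.tr

    def volume_labels(self) -> list[str | None]:
        """Per-volume condition label (None where no condition applies)."""
        labels: list[str | None] = [None] * self.n_volumes
        mid = (np.arange(self.n_volumes) + 0.5) * self.tr
        for c in self.conditions:
            inside = (mid >= c.onset_s) & (mid < c.onset_s + c.duration_s)
            for t in np.nonzero(inside)[0]:
                labels[t] = c.label
        return labels

    def pair_labels(self) -> list[str | None]:
        """Condition of each consecutive-volume pair (t, t+1).

        A pair is assigned to a condition only when both of its volumes
        carry that condition's label; pairs spanning a block boundary are
        dropped (None) so blink transitions do not contaminate rest blocks.
        """
        v = self.volume_labels()
        return [
            v[t] if v[t] is not None and v[t] == v[t + 1] else None
            for t in range(self.n_volumes - 1)
        ]


def blinking_paradigm(
    tr: float = 1.5,
    block_duration_s: float = 20.0,
    n_cycles: float = 7.5,
    on_label: str = "on",
    off_label: str = "off",
) -> BlockDesign:
    """The forceful-blinking paradigm: alternating 20 s on / 20 s off blocks.

    7.5 cycles of (20 s forceful blinking + 20 s natural-blinking rest)
    span 5 minutes — exactly 200 volumes at TR = 1.5 s — ending on a final
    half-cycle (an on block with no closing rest).
    """
    total_s = n_cycles * 2 * block_duration_s
    n_volumes = round(total_s / tr)
    if abs(n_volumes * tr - total_s) > 1e-6:
        raise ParameterError(
            f"paradigm duration {total_s:g} s is not a whole number of TRs"
        )
    conditions = []
    t = 0.0
    label = on_label
    while t < total_s - 1e-9:
        dur = min(block_duration_s, total_s - t)
        conditions.append(Condition(label, t, dur))
        t += dur
        label = off_label if label == on_label else on_label
    return BlockDesign(tr=tr, n_volumes=n_volumes, conditions=tuple(conditions))


@dataclass(frozen=True)
class IntensityReport:
    """Artefact intensity at one region: on/off mean |percent change|."""

    label: str
    on_mean: float
    off_mean: float
    n_diffs_on: int
    n_diffs_off: int
    kind: str = ""

    @property
    def difference(self) -> float:
        return self.on_mean - self.off_mean


def _check_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series)
    if series.shape[-1] < 2:
        raise InputError(
            f"need at least 2 volumes along the time axis, got {series.shape[-1]}"
        )
    return series


def variance_map(series: np.ndarray) -> np.ndarray:
    """Per-voxel sample variance (ddof=1) over the full time axis."""
    series = _check_series(series)
    return np.var(series.astype(np.float64), axis=-1, ddof=1)


def percent_signal_change(series: np.ndarray) -> np.ndarray:
    """Volume-to-volume signal change as a percentage of the per-voxel maximum.

    For each voxel, d(t) = S(t+1) - S(t) is divided by max_t |d(t)| taken
    over the entire time series, times 100.  Constant voxels (zero maximum
    change) yield identically zero rather than undefined values.  The
    result has one fewer sample than the input along the time axis and
    satisfies |p| <= 100 with equality at the argmax.
    """
    series = _check_series(series).astype(np.float64)
    d = np.diff(series, axis=-1)
    peak = np.max(np.abs(d), axis=-1, keepdims=True)
    safe = np.where(peak == 0, 1.0, peak)
    p = 100.0 * d / safe
    return np.where(peak == 0, 0.0, p)


def _mask_series(series: np.ndarray, mask: RegionMask) -> np.ndarray:
    if series.ndim != 4:
        raise InputError(f"expected a 4D series, got {series.ndim} dimensions")
    xs, ys, zs = mask.indices()
    for axis, idx in enumerate((xs, ys, zs)):
        if idx.size and (idx.min() < 0 or idx.max() >= series.shape[axis]):
            raise InputError(
                f"mask {mask.label!r} exceeds the series grid "
                f"{series.shape[:3]} on axis {axis}"
            )
    return series[xs, ys, zs, :]  # (n_voxels, T)


def artefact_intensity(
    series: np.ndarray,
    mask: RegionMask,
    design: BlockDesign,
    on_label: str = "on",
    off_label: str = "off",
    kind: str = "",
) -> IntensityReport:
    """Mean absolute percentage signal change in a mask, on vs off blocks.

    Every consecutive-volume difference of every mask voxel is converted
    to a percentage of that voxel's maximum absolute change, assigned to a
    condition when both volumes of the pair share it, and averaged (as
    absolute values) over voxels x pairs separately for the on and off
    conditions.  The artefact intensity is ``on_mean - off_mean``.
    """
    series = _check_series(series)
    if design.n_volumes != series.shape[-1]:
        raise InputError(
            f"design covers {design.n_volumes} volumes but the series has "
            f"{series.shape[-1]}"
        )
    vox = _mask_series(series, mask)
    p = percent_signal_change(vox)
    pairs = design.pair_labels()
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for label in (on_label, off_label):
        sel = [t for t, lab in enumerate(pairs) if lab == label]
        if not sel:
            raise ComputationError(
                f"condition {label!r} has no usable volume pairs "
                "(pairs spanning block boundaries are dropped)"
            )
        means[label] = float(np.mean(np.abs(p[:, sel])))
        counts[label] = len(sel)
    return IntensityReport(
        label=mask.label,
        on_mean=means[on_label],
        off_mean=means[off_label],
        n_diffs_on=counts[on_label],
        n_diffs_off=counts[off_label],
        kind=kind,
    )


def region_report(
    series: np.ndarray | list[np.ndarray],
    masks: list[RegionMask],
    design: BlockDesign,
    on_label: str = "on",
    off_label: str = "off",
    kinds: list[str] | None = None,
) -> pd.DataFrame:
    """Artefact-intensity table, one row per region.

    When several series (e.g. subjects) are given, per-region means and
    standard errors of the mean across series are appended.
    """
    series_list = series if isinstance(series, list) else [series]
    if kinds is None:
        kinds = [""] * len(masks)
    rows = []
    for i, s in enumerate(series_list):
        for mask, kind in zip(masks, kinds):
            rep = artefact_intensity(s, mask, design, on_label, off_label, kind)
            rows.append(
                {
                    "series": i,
                    "region": rep.label,
                    "kind": rep.kind,
                    "on_mean_pct": rep.on_mean,
                    "off_mean_pct": rep.off_mean,
                    "difference_pct": rep.difference,
                    "n_on_pairs": rep.n_diffs_on,
                    "n_off_pairs": rep.n_diffs_off,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "series",
            "region",
            "kind",
            "on_mean_pct",
            "off_mean_pct",
            "difference_pct",
            "n_on_pairs",
            "n_off_pairs",
        ],
    )
    if len(series_list) == 1:
        return df.drop(columns="series")
    return df


def aggregate_reports(report: pd.DataFrame) -> pd.DataFrame:
    """Across-series mean +/- SEM of the intensity difference per region."""
    if "series" not in report.columns:
        raise InputError("aggregate_reports expects a multi-series report")
    g = report.groupby("region", sort=False)["difference_pct"]
    out = g.agg(difference_mean="mean", difference_sem="sem", n_series="count")
    return out.reset_index()
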