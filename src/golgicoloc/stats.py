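"""Cohort statistics, significance tests and linescans.

The cohort unit is the cell: per-cell coefficients are summarized as
mean +/- SEM (sample standard deviation, n-1 denominator), and groups are
compared with unpaired two-tailed t-tests (Welch by default; Student's
available).  Linescans sample per-channel intensities along a segment of one
z-plane by bilinear interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats as sps

from .coloc import CalibrationBands, classify_coefficient
from .optics import ImageStack

__all__ = [
    "CohortSummary",
    "LinescanProfile",
    "aggregate_cells",
    "classify_cohort",
    "ttest_unpaired",
    "linescan",
]


@dataclass
class CohortSummary:
    """Mean +/- SEM of per-cell coefficients for one condition."""

    label: str
    n: int
    mean: float
    sem: Optional[float]
    values: np.ndarray
    n_excluded: int = 0


def aggregate_cells(values: Sequence[Optional[float]], label: str = "") -> CohortSummary:
    """Summarize per-cell coefficients as mean +/- SEM.

    Undefined per-cell values (None or NaN, e.g. empty-channel cells) are
    excluded and counted; SEM is undefined (None) for n = 1.
    """
    vals = np.array(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    n_excluded = len(list(values)) - vals.size
    if vals.size == 0:
        raise ValueError("no defined per-cell values after exclusions")
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
    return CohortSummary(
        label=label,
        n=int(vals.size),
        mean=float(vals.mean()),
        sem=sem,
        values=vals,
        n_excluded=n_excluded,
    )


def classify_cohort(summary: CohortSummary, bands: CalibrationBands) -> str:
    """Classify a cohort by its mean coefficient (the unit used for bar
    charts): negligible / moderate / high."""
    return classify_coefficient(summary.mean, bands)


def ttest_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test; returns (t, p, df).

    ``variant`` is "welch" (default, unequal variances) or "student".  Zero
    pooled variance with equal means returns (0, 1, df) by convention; with
    different means it returns (+/-inf, 0, df).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return (0.0, 1.0, df)
        return (math.copysign(math.inf, a.mean() - b.mean()), 0.0, df)
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return (float(res.statistic), float(res.pvalue), float(res.df))


@dataclass
class LinescanProfile:
    """Per-channel intensity profile along a segment of one z-plane."""

    positions_nm: np.ndarray
    intensities: dict[str, np.ndarray]
    p0_nm: tuple[float, float]
    p1_nm: tuple[float, float]
    z_index: int


def linescan(
    stack: ImageStack,
    p0_nm: Sequence[float],
    p1_nm: Sequence[float],
    z_index: int,
    channels: Optional[Sequence[str]] = None,
) -> LinescanProfile:
    """Sample intensities along the segment p0 -> p1 ((y, x) in nm) in one
    z-plane, at half-pixel spacing, by bilinear interpolation.

    A zero-length segment yields a single sample at p0.
    """
    p0 = np.asarray(p0_nm, dtype=float)
    p1 = np.asarray(p1_nm, dtype=float)
    if not (0 <= z_index < stack.data.shape[1]):
        raise ValueError("z_index outside the stack")
    vz, vy, vx = stack.voxel_nm
    ny, nx = stack.data.shape[2:]
    for p in (p0, p1):
        if not (0 <= p[0] <= ny * vy and 0 <= p[1] <= nx * vx):
            raise ValueError(f"endpoint {tuple(p)} outside the field")
    length = float(np.hypot(*(p1 - p0)))
    spacing = min(vy, vx) / 2.0
    n = max(1, int(np.ceil(length / spacing)) + 1)
    ts = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    # physical nm -> fractional pixel index (pixel centers at (i + 0.5) * v)
    coords = np.vstack([pts[:, 0] / vy - 0.5, pts[:, 1] / vx - 0.5])
    names = list(channels) if channels is not None else list(stack.channel_names)
    intensities = {
        name: ndimage.map_coordinates(
            stack.channel(name)[z_index].astype(np.float64),
            coords,
            order=1,
            mode="nearest",
        )
        for name in names
    }
    return LinescanProfile(
        positions_nm=ts * length,
        intensities=intensities,
        p0_nm=tuple(p0),
        p1_nm=tuple(p1),
        z_index=int(z_index),
    )
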