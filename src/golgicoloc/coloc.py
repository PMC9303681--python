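"""Mask-restricted directional volume colocalization.

The central statistic is a Manders-style pair of binary-volume coefficients
computed inside a region mask built from marker channels:

    coefficient 1 = V(A and B) / V(A)      (A-over-B)
    coefficient 2 = V(A and B) / V(B)      (B-over-A)

where V() is the voxel count of the segmented binary volume restricted to the
region.  Volumes are integer voxel counts, so coefficient1 * V(A) =
V(A and B) = coefficient2 * V(B) holds exactly.  An empty channel inside the
region leaves the corresponding coefficient undefined (None), never zero.

Calibration bands turn raw coefficients into the categories negligible /
moderate / high.  The band values are means over control marker pairs: a
cis-versus-trans Golgi pair defines the negligible background, two distinct
trans-Golgi markers the moderate level, and dual antibody staining of a
single protein the perfect level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .segmentation import ChannelSurfaces, surfaces_from_mask

__all__ = [
    "RegionMask",
    "ColocResult",
    "CalibrationBands",
    "CalibrationError",
    "make_region_mask",
    "restrict_to_region",
    "full_domain_region",
    "coloc_coefficients",
    "compartment_volumes",
    "calibrate_bands",
    "classify_coefficient",
    "reference_bands",
]


class CalibrationError(ValueError):
    """Control-pair coefficients violate the band ordering invariant."""


@dataclass
class RegionMask:
    """Binary region (e.g. "TGN" = union of two trans-Golgi markers)."""

    mask: np.ndarray
    label: str
    markers: list[str] = field(default_factory=list)
    empty: bool = False

    @property
    def volume_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ColocResult:
    """Directional volume colocalization inside one region of one cell.

    ``coefficient1``/``coefficient2`` are None when the corresponding channel
    is empty inside the region (flagged via ``empty_a``/``empty_b``).
    """

    vol_a: int
    vol_b: int
    vol_ab: int
    region: str = "full"
    cell_id: str = ""
    channel_a: str = "A"
    channel_b: str = "B"

    @property
    def empty_a(self) -> bool:
        return self.vol_a == 0

    @property
    def empty_b(self) -> bool:
        return self.vol_b == 0

    @property
    def coefficient1(self) -> Optional[float]:
        return None if self.vol_a == 0 else self.vol_ab / self.vol_a

    @property
    def coefficient2(self) -> Optional[float]:
        return None if self.vol_b == 0 else self.vol_ab / self.vol_b


def _check_same_grid(*shapes) -> None:
    if len({tuple(s) for s in shapes}) != 1:
        raise ValueError(f"voxel grids do not match: {shapes}")


def make_region_mask(markers: Sequence[ChannelSurfaces], label: str) -> RegionMask:
    """Union of one or more segmented marker channels."""
    if not markers:
        raise ValueError("need at least one marker channel")
    _check_same_grid(*(m.mask.shape for m in markers))
    mask = np.zeros(markers[0].mask.shape, dtype=bool)
    for m in markers:
        mask |= m.mask
    return RegionMask(
        mask=mask,
        label=label,
        markers=[m.channel for m in markers],
        empty=not mask.any(),
    )


def full_domain_region(shape, label: str = "full") -> RegionMask:
    """The whole voxel grid as a region (unrestricted colocalization)."""
    return RegionMask(mask=np.ones(shape, dtype=bool), label=label)


def restrict_to_region(surfaces: ChannelSurfaces, region: RegionMask) -> ChannelSurfaces:
    """Intersect a channel's surfaces with a region mask and relabel the
    components.  No size filter is re-applied."""
    _check_same_grid(surfaces.mask.shape, region.mask.shape)
    return surfaces_from_mask(
        surfaces.mask & region.mask,
        surfaces.voxel_nm,
        channel=surfaces.channel,
        params=surfaces.params,
    )


def coloc_coefficients(
    a: ChannelSurfaces,
    b: ChannelSurfaces,
    region: Optional[RegionMask] = None,
    cell_id: str = "",
) -> ColocResult:
    """Directional volume coefficients of two channels inside a region.

    ``region=None`` means the full domain.
    """
    _check_same_grid(a.mask.shape, b.mask.shape)
    if region is None:
        region = full_domain_region(a.mask.shape)
    else:
        _check_same_grid(a.mask.shape, region.mask.shape)
    ra = a.mask & region.mask
    rb = b.mask & region.mask
    return ColocResult(
        vol_a=int(ra.sum()),
        vol_b=int(rb.sum()),
        vol_ab=int((ra & rb).sum()),
        region=region.label,
        cell_id=cell_id,
        channel_a=a.channel or "A",
        channel_b=b.channel or "B",
    )


def compartment_volumes(
    channels: Sequence[ChannelSurfaces], region: RegionMask
) -> pd.DataFrame:
    """Voxel volume of each channel restricted to the region."""
    _check_same_grid(*(c.mask.shape for c in channels), region.mask.shape)
    return pd.DataFrame(
        {
            "channel": [c.channel for c in channels],
            "region": region.label,
            "voxels": [int((c.mask & region.mask).sum()) for c in channels],
        }
    )


@dataclass(frozen=True)
class CalibrationBands:
    """Coefficient thresholds calibrated from control marker pairs."""

    negligible_max: float
    moderate_max: float
    perfect_min: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.negligible_max < self.moderate_max < self.perfect_min <= 1.0):
            raise CalibrationError(
                "bands must satisfy 0 < negligible < moderate < perfect <= 1, got "
                f"({self.negligible_max}, {self.moderate_max}, {self.perfect_min})"
            )


def _mean_coeffs(pairs) -> float:
    vals = []
    for p in pairs:
        if isinstance(p, ColocResult):
            for c in (p.coefficient1, p.coefficient2):
                if c is not None:
                    vals.append(c)
        else:
            vals.append(float(p))
    if not vals:
        raise CalibrationError("empty control-pair list")
    return float(np.mean(vals))


def calibrate_bands(
    negligible_pairs, moderate_pairs, perfect_pairs
) -> CalibrationBands:
    """Derive classification bands from three lists of control measurements.

    Each list may hold raw coefficients or :class:`ColocResult` objects; the
    band value is the mean over the list.  The ordering invariant is enforced
    (violations raise :class:`CalibrationError`).
    """
    neg = _mean_coeffs(negligible_pairs)
    mod = _mean_coeffs(moderate_pairs)
    per = _mean_coeffs(perfect_pairs)
    return CalibrationBands(
        negligible_max=neg,
        moderate_max=mod,
        perfect_min=per,
        provenance={
            "negligible_n": len(list(negligible_pairs)),
            "moderate_n": len(list(moderate_pairs)),
            "perfect_n": len(list(perfect_pairs)),
        },
    )


def reference_bands() -> CalibrationBands:
    """Bands calibrated from the published HeLa control pairs: cis (GM130)
    vs trans (GCC88) markers 0.16/0.22 (negligible), the two trans markers
    GCC88 vs golgin97 0.52/0.59 (moderate), and dual-antibody GM130 staining
    0.99/1.0 (perfect)."""
    return calibrate_bands([0.16, 0.22], [0.52, 0.59], [0.99, 1.0])


def classify_coefficient(c: float, bands: CalibrationBands) -> str:
    """Classify a coefficient as negligible / moderate / high.

    Boundary ties are inclusive-below: a value exactly at a band edge takes
    the lower category.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"coefficient must be in [0, 1], got {c}")
    if c <= bands.negligible_max:
        return "negligible"
    if c <= bands.moderate_max:
        return "moderate"
    return "high"
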