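"""Dispersed Golgi ministack detection and cargo co-occurrence.

After microtubule depolymerization (nocodazole) the Golgi ribbon breaks into
individual ministacks scattered through the cytoplasm.  A ministack is a
connected component of the Golgi region mask (union of the cisternal marker
channels).  Each stack is classified by which cargoes it contains: a cargo
is present if at least ``presence_min`` of its segmented voxels fall inside
the stack (default 2; a 1-voxel criterion is shot-noise fragile).  Stacks
touching the image border are retained but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .coloc import RegionMask
from .segmentation import ChannelSurfaces, _structure

__all__ = ["MinistackTable", "detect_ministacks", "classify_cooccurrence", "CATEGORIES"]

CATEGORIES = ("both", "A_only", "B_only", "neither")


@dataclass
class MinistackDetection:
    """Labelled ministacks: label field plus a per-stack table
    (stack_id, voxels, centroid nm, touches_border)."""

    labels: np.ndarray
    table: pd.DataFrame
    empty: bool = False

    @property
    def n_stacks(self) -> int:
        return len(self.table)


@dataclass
class MinistackTable:
    """Per-ministack cargo presence and cohort category fractions."""

    table: pd.DataFrame
    fractions: dict
    presence_min: int
    cell_id: str = ""
    empty: bool = False
    flags: dict = field(default_factory=dict)


def detect_ministacks(
    golgi_region: RegionMask,
    connectivity: int = 26,
    min_component_voxels: int = 4,
    voxel_nm=(159.0, 35.0, 35.0),
) -> MinistackDetection:
    """Connected components of the Golgi region mask.

    Components below ``min_component_voxels`` are discarded.  An empty region
    yields an empty, flagged detection.
    """
    structure = _structure(connectivity)
    labels, n = ndimage.label(golgi_region.mask, structure=structure)
    if n == 0:
        return MinistackDetection(
            labels=labels.astype(np.int32),
            table=pd.DataFrame(
                columns=["stack_id", "voxels", "z_nm", "y_nm", "x_nm", "touches_border"]
            ),
            empty=True,
        )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    small = np.nonzero(counts[1:] < min_component_voxels)[0] + 1
    if small.size:
        labels[np.isin(labels, small)] = 0
        labels, n = ndimage.label(labels > 0, structure=structure)
        counts = np.bincount(labels.ravel(), minlength=n + 1)

    border = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    border_ids = set(np.unique(labels[border])) - {0}

    coms = ndimage.center_of_mass(labels > 0, labels, index=np.arange(1, n + 1))
    coms = np.atleast_2d(np.asarray(coms, dtype=float))
    vz, vy, vx = voxel_nm
    table = pd.DataFrame(
        {
            "stack_id": np.arange(1, n + 1),
            "voxels": counts[1:].astype(int),
            "z_nm": (coms[:, 0] + 0.5) * vz,
            "y_nm": (coms[:, 1] + 0.5) * vy,
            "x_nm": (coms[:, 2] + 0.5) * vx,
            "touches_border": [i in border_ids for i in range(1, n + 1)],
        }
    )
    return MinistackDetection(labels=labels.astype(np.int32), table=table, empty=n == 0)


def classify_cooccurrence(
    stacks: MinistackDetection,
    a: ChannelSurfaces,
    b: ChannelSurfaces,
    presence_min: int = 2,
    cell_id: str = "",
) -> MinistackTable:
    """Classify each ministack as both / A_only / B_only / neither.

    A cargo is present in a stack iff at least ``presence_min`` of its
    segmented voxels intersect the stack (an overlap of presence_min - 1
    voxels counts as absent).  Cohort fractions are computed over all
    retained stacks and sum to one.
    """
    if presence_min < 1:
        raise ValueError("presence_min must be >= 1")
    if stacks.empty or stacks.n_stacks == 0:
        return MinistackTable(
            table=pd.DataFrame(
                columns=[
                    "stack_id", "voxels", "z_nm", "y_nm", "x_nm",
                    "touches_border", "overlap_a", "overlap_b",
                    "contains_a", "contains_b", "category",
                ]
            ),
            fractions={c: float("nan") for c in CATEGORIES},
            presence_min=presence_min,
            cell_id=cell_id,
            empty=True,
        )
    labels = stacks.labels
    n = stacks.n_stacks
    ids = stacks.table["stack_id"].to_numpy()
    ov_a = ndimage.sum_labels(a.mask.astype(np.int64), labels, index=ids).astype(int)
    ov_b = ndimage.sum_labels(b.mask.astype(np.int64), labels, index=ids).astype(int)
    contains_a = ov_a >= presence_min
    contains_b = ov_b >= presence_min
    category = np.where(
        contains_a & contains_b,
        "both",
        np.where(contains_a, "A_only", np.where(contains_b, "B_only", "neither")),
    )
    table = stacks.table.copy()
    table["overlap_a"] = ov_a
    table["overlap_b"] = ov_b
    table["contains_a"] = contains_a
    table["contains_b"] = contains_b
    table["category"] = category
    fractions = {c: float((category == c).sum()) / n for c in CATEGORIES}
    return MinistackTable(
        table=table,
        fractions=fractions,
        presence_min=presence_min,
        cell_id=cell_id,
        flags={"empty_a": a.empty, "empty_b": b.empty},
    )
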