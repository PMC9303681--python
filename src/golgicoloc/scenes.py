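"""Synthetic cell scenes with voxel-level ground truth.

Occupancy fields are built on a fine isotropic grid (default 10 nm, i.e. at
least 3x oversampling of the 35 nm acquisition pixel) for several geometries:

``ribbon``
    One curved Golgi stack sheet: cisternal marker layers (cis / medial /
    trans) stacked along the stack axis, cargo proteins partitioned into
    lateral membrane subdomains.
``ministacks``
    Nocodazole-style dispersal: ``n_ministacks`` disjoint mini-stacks, each
    carrying every cisternal layer, scattered through the cytoplasm.
``er_bfa`` / ``er_rush``
    A tubular ER network carrying both cargoes (brefeldin-A relocation or
    RUSH retention regimes; RUSH co-retention corresponds to ``mixing = 1``).
``beads``
    Sub-resolution calibration beads (default 100 nm diameter) on one
    z-plane, for point-spread-function measurements.

The degree of cargo co-assignment is controlled by ``mixing`` (phi): each
lateral subdomain is *shared* with probability phi (one occupancy draw places
both cargoes together) and otherwise assigned exclusively to cargo A or B
with equal probability.  phi = 0 gives fully segregated cargoes, phi = 1
identical cargo fields.

Arrays are ordered (z, y, x); all physical tuples use the same order, in nm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "BeadSpec",
    "OrganelleSpec",
    "SceneValidationError",
    "PlacementError",
    "build_scene",
    "true_overlap_fractions",
    "CARGO_A",
    "CARGO_B",
    "ORGANELLE",
]

CARGO_A = "cargoA"
CARGO_B = "cargoB"
ORGANELLE = "organelle"

#: per-ministack cargo co-occurrence categories, in the order used by
#: ``SceneSpec.category_probs``.
CATEGORIES = ("both", "A_only", "B_only", "neither")


class SceneValidationError(ValueError):
    """A scene specification violates one of its invariants."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place objects within the retry budget."""


@dataclass(frozen=True)
class BeadSpec:
    """Calibration-bead layout: ``count`` spheres of ``diameter_nm`` placed on
    the central z-plane with pairwise lateral separation of at least
    ``min_separation_nm`` (keep this above twice the optical FWHM so bead
    profiles do not overlap)."""

    count: int = 12
    diameter_nm: float = 100.0
    min_separation_nm: float = 600.0


@dataclass(frozen=True)
class OrganelleSpec:
    """Extra spherical organelles (lysosome-like), placed uniformly at random
    in the field, spatially independent of the Golgi."""

    count: int = 0
    radius_nm: float = 250.0


_DEFAULT_OFFSETS: Mapping[str, float] = {"cis": 0.0, "medial": 150.0, "trans": 300.0}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Attributes
    ----------
    mode : {"ribbon", "ministacks", "er_bfa", "er_rush", "beads"}
    field_size_nm : (z, y, x) physical extents in nm.  The default z extent
        equals nine 159-nm acquisition sections.
    fine_grid_step_nm : isotropic ground-truth grid step; must oversample the
        acquisition voxel by at least 3x.
    cisternal_offsets_nm : marker name -> axial offset within a stack.
    cargo_offset_nm : axial offset of the cisterna that carries both cargoes
        (default: the trans cisterna).
    mixing : phi in [0, 1], degree of cargo co-assignment to subdomains.
    subdomain_scale_nm : lateral size of the square membrane patches.
    cargo_density : occupancy probability per subdomain per cargo.
    category_probs : optional (p_both, p_A_only, p_B_only, p_neither) for
        ministacks mode; when given, per-stack cargo presence is drawn from
        these categories directly instead of through the subdomain mixing.
    stack_axis : "z" (default) or "y"; "y" builds a side-on straight ribbon
        whose cisternae are resolved laterally (for linescans).
    """

    mode: str = "ribbon"
    field_size_nm: tuple[float, float, float] = (1431.0, 6000.0, 6000.0)
    fine_grid_step_nm: float = 10.0
    n_ministacks: int = 12
    cisternal_offsets_nm: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSETS)
    )
    cargo_offset_nm: float = 300.0
    mixing: float = 0.5
    subdomain_scale_nm: float = 150.0
    cargo_density: float = 0.6
    layer_thickness_nm: float = 150.0
    ribbon_radius_nm: float = 1800.0
    ribbon_width_nm: float = 600.0
    ribbon_span_deg: float = 160.0
    ribbon_length_nm: float = 2500.0
    stack_axis: str = "z"
    ministack_radius_nm: float = 300.0
    ministack_min_separation_nm: float = 1500.0
    placement_retries: int = 1000
    er_n_tubules: int = 8
    er_tubule_radius_nm: float = 60.0
    category_probs: Optional[tuple[float, float, float, float]] = None
    organelles: OrganelleSpec = field(default_factory=OrganelleSpec)
    beads: BeadSpec = field(default_factory=BeadSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("ribbon", "ministacks", "er_bfa", "er_rush", "beads"):
            raise SceneValidationError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.mixing <= 1.0):
            raise SceneValidationError(f"mixing must be in [0, 1], got {self.mixing}")
        if any(e <= 0 for e in self.field_size_nm):
            raise SceneValidationError("field extents must be positive")
        if self.fine_grid_step_nm <= 0:
            raise SceneValidationError("fine_grid_step_nm must be positive")
        if not (0.0 <= self.cargo_density <= 1.0):
            raise SceneValidationError("cargo_density must be in [0, 1]")
        offs = list(self.cisternal_offsets_nm.values())
        if len(set(offs)) != len(offs):
            raise SceneValidationError("cisternal offsets must be distinct per marker")
        if self.category_probs is not None:
            p = np.asarray(self.category_probs, dtype=float)
            if p.size != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise SceneValidationError(
                    "category_probs must be 4 non-negative values summing to 1"
                )
        if self.stack_axis not in ("z", "y"):
            raise SceneValidationError("stack_axis must be 'z' or 'y'")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        h = self.fine_grid_step_nm
        return tuple(max(1, int(round(e / h))) for e in self.field_size_nm)


@dataclass
class GroundTruth:
    """Per-channel binary occupancy on the fine grid, plus scene metadata.

    ``true_overlap`` is (|A∩B|/|A|, |A∩B|/|B|) for the two cargo channels,
    counted on the fine grid ((0, 0) with ``empty_channels`` flagged when a
    cargo field is empty).
    """

    channels: dict[str, np.ndarray]
    spec: SceneSpec
    seed: int
    true_overlap: Optional[tuple[float, float]] = None
    empty_channels: set = field(default_factory=set)
    ministack_labels: Optional[np.ndarray] = None
    ministack_table: Optional[pd.DataFrame] = None
    bead_centers_nm: Optional[np.ndarray] = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def fine_step_nm(self) -> float:
        return self.spec.fine_grid_step_nm


# ---------------------------------------------------------------------------
# low-level helpers


def _axis_centers(n: int, step: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * step


def _paint_sphere(occ: np.ndarray, center_nm, radius_nm: float, step: float) -> None:
    """Set occ voxels whose centers lie within radius_nm of center_nm."""
    if radius_nm <= 0:
        idx = tuple(min(occ.shape[i] - 1, max(0, int(center_nm[i] / step))) for i in range(3))
        occ[idx] = True
        return
    lo = [max(0, int((center_nm[i] - radius_nm) / step) - 1) for i in range(3)]
    hi = [min(occ.shape[i], int((center_nm[i] + radius_nm) / step) + 2) for i in range(3)]
    if any(l >= h for l, h in zip(lo, hi)):
        return
    ax = [
        _axis_centers(occ.shape[i], step)[lo[i] : hi[i]] - center_nm[i] for i in range(3)
    ]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius_nm**2


def _place_points_2d(
    n: int,
    low,
    high,
    min_separation: float,
    rng: np.random.Generator,
    retries: int,
) -> np.ndarray:
    """Rejection-sample n (y, x) points with a minimum pairwise distance."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts > retries:
            raise PlacementError(
                f"placed {len(pts)}/{n} points within {retries} retries "
                f"(min separation {min_separation} nm)"
            )
        cand = rng.uniform(low, high)
        attempts += 1
        if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
            pts.append(cand)
    return np.array(pts)


def _assign_subdomains(
    patch_ids: np.ndarray,
    rng: np.random.Generator,
    mixing: float,
    density: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign cargo occupancy to subdomain patches.

    Each unique patch is shared with probability ``mixing`` (a single
    occupancy draw then places *both* cargoes, modelling co-assignment) and
    otherwise exclusive to one cargo (50:50).  Returns the patch-id sets
    occupied by cargo A and cargo B.
    """
    uniq = np.unique(patch_ids)
    shared = rng.random(uniq.size) < mixing
    a_side = rng.random(uniq.size) < 0.5
    occ_shared = rng.random(uniq.size) < density
    occ_excl = rng.random(uniq.size) < density
    sel_a = uniq[(shared & occ_shared) | (~shared & a_side & occ_excl)]
    sel_b = uniq[(shared & occ_shared) | (~shared & ~a_side & occ_excl)]
    return sel_a, sel_b


def _patch_grid_2d(shape_yx, step: float, scale: float) -> np.ndarray:
    """Integer patch id per lateral fine voxel (square tessellation)."""
    ny, nx = shape_yx
    yi = (_axis_centers(ny, step) // scale).astype(np.int64)
    xi = (_axis_centers(nx, step) // scale).astype(np.int64)
    return yi[:, None] * (xi.max() + 1) + xi[None, :]


# ---------------------------------------------------------------------------
# mode builders


def _stack_base(spec: SceneSpec, extent: float) -> float:
    offs = list(spec.cisternal_offsets_nm.values())
    return extent / 2.0 - (min(offs) + max(offs)) / 2.0


def _layer_window(centers: np.ndarray, center_nm: float, thickness: float) -> np.ndarray:
    return np.abs(centers - center_nm) <= thickness / 2.0


def _build_ribbon(spec: SceneSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    nz, ny, nx = spec.grid_shape
    h = spec.fine_grid_step_nm
    fz, fy, fx = spec.field_size_nm

    if spec.stack_axis == "y":
        return _build_ribbon_side_on(spec, rng)

    yc = _axis_centers(ny, h)
    xc = _axis_centers(nx, h)
    r = np.hypot(yc[:, None] - fy / 2.0, xc[None, :] - fx / 2.0)
    ang = np.degrees(np.arctan2(yc[:, None] - fy / 2.0, xc[None, :] - fx / 2.0))
    dang = np.abs(((ang - 90.0) + 180.0) % 360.0 - 180.0)
    in_band = (np.abs(r - spec.ribbon_radius_nm) <= spec.ribbon_width_nm / 2.0) & (
        dang <= spec.ribbon_span_deg / 2.0
    )

    zc = _axis_centers(nz, h)
    base = _stack_base(spec, fz)
    channels: dict[str, np.ndarray] = {}
    for name, off in spec.cisternal_offsets_nm.items():
        zwin = _layer_window(zc, base + off, spec.layer_thickness_nm)
        channels[name] = zwin[:, None, None] & in_band[None]

    _add_cargo_2d(channels, spec, rng, in_band, zc, base)
    return channels


def _build_ribbon_side_on(spec: SceneSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Straight ribbon with the stack axis along y: cisternae are separated
    laterally, so an in-plane linescan crosses cis -> medial -> trans."""
    nz, ny, nx = spec.grid_shape
    h = spec.fine_grid_step_nm
    fz, fy, fx = spec.field_size_nm

    zc = _axis_centers(nz, h)
    yc = _axis_centers(ny, h)
    xc = _axis_centers(nx, h)
    in_x = np.abs(xc - fx / 2.0) <= spec.ribbon_length_nm / 2.0
    in_z = np.abs(zc - fz / 2.0) <= spec.ribbon_width_nm / 2.0
    base = _stack_base(spec, fy)

    channels: dict[str, np.ndarray] = {}
    for name, off in spec.cisternal_offsets_nm.items():
        ywin = _layer_window(yc, base + off, spec.layer_thickness_nm)
        channels[name] = in_z[:, None, None] & ywin[None, :, None] & in_x[None, None, :]

    # cargoes share the trans-most plane; subdomains tessellate (z, x)
    if spec.cargo_density > 0:
        zi = (zc // spec.subdomain_scale_nm).astype(np.int64)
        xi = (xc // spec.subdomain_scale_nm).astype(np.int64)
        pid = zi[:, None] * (xi.max() + 1) + xi[None, :]
        sheet = in_z[:, None] & in_x[None, :]
        sel_a, sel_b = _assign_subdomains(pid[sheet], rng, spec.mixing, spec.cargo_density)
        ywin_c = _layer_window(yc, base + spec.cargo_offset_nm, spec.layer_thickness_nm)
        lat_a = sheet & np.isin(pid, sel_a)
        lat_b = sheet & np.isin(pid, sel_b)
        channels[CARGO_A] = ywin_c[None, :, None] & lat_a[:, None, :]
        channels[CARGO_B] = ywin_c[None, :, None] & lat_b[:, None, :]
    else:
        channels[CARGO_A] = np.zeros((nz, ny, nx), dtype=bool)
        channels[CARGO_B] = np.zeros((nz, ny, nx), dtype=bool)
    return channels


def _add_cargo_2d(channels, spec, rng, in_band, zc, base) -> None:
    nz = zc.size
    ny, nx = in_band.shape
    if spec.cargo_density > 0:
        pid = _patch_grid_2d((ny, nx), spec.fine_grid_step_nm, spec.subdomain_scale_nm)
        sel_a, sel_b = _assign_subdomains(
            pid[in_band], rng, spec.mixing, spec.cargo_density
        )
        zwin_c = _layer_window(zc, base + spec.cargo_offset_nm, spec.layer_thickness_nm)
        lat_a = in_band & np.isin(pid, sel_a)
        lat_b = in_band & np.isin(pid, sel_b)
        channels[CARGO_A] = zwin_c[:, None, None] & lat_a[None]
        channels[CARGO_B] = zwin_c[:, None, None] & lat_b[None]
    else:
        channels[CARGO_A] = np.zeros((nz, ny, nx), dtype=bool)
        channels[CARGO_B] = np.zeros((nz, ny, nx), dtype=bool)


def _build_ministacks(spec: SceneSpec, rng: np.random.Generator):
    nz, ny, nx = spec.grid_shape
    h = spec.fine_grid_step_nm
    fz, fy, fx = spec.field_size_nm
    margin = spec.ministack_radius_nm + 200.0
    if fy <= 2 * margin or fx <= 2 * margin:
        raise SceneValidationError("field too small for ministack placement margin")
    centers = _place_points_2d(
        spec.n_ministacks,
        (margin, margin),
        (fy - margin, fx - margin),
        spec.ministack_min_separation_nm,
        rng,
        spec.placement_retries,
    )

    yc = _axis_centers(ny, h)
    xc = _axis_centers(nx, h)
    lab2d = np.zeros((ny, nx), dtype=np.int32)
    for k, (cy, cx) in enumerate(centers, start=1):
        d2 = (yc[:, None] - cy) ** 2 + (xc[None, :] - cx) ** 2
        lab2d[d2 <= spec.ministack_radius_nm**2] = k

    zc = _axis_centers(nz, h)
    base = _stack_base(spec, fz)
    channels: dict[str, np.ndarray] = {}
    disk_any = lab2d > 0
    for name, off in spec.cisternal_offsets_nm.items():
        zwin = _layer_window(zc, base + off, spec.layer_thickness_nm)
        channels[name] = zwin[:, None, None] & disk_any[None]

    # 3D stack labels: the cylinder spanning all cisternal layers
    offs = list(spec.cisternal_offsets_nm.values())
    t = spec.layer_thickness_nm
    zspan = (zc >= base + min(offs) - t / 2.0) & (zc <= base + max(offs) + t / 2.0)
    labels3d = np.where(zspan[:, None, None], lab2d[None, :, :], 0).astype(np.int32)

    pid = _patch_grid_2d((ny, nx), h, spec.subdomain_scale_nm)
    n = spec.n_ministacks
    contains_a = np.zeros(n, dtype=bool)
    contains_b = np.zeros(n, dtype=bool)
    lat_a = np.zeros((ny, nx), dtype=bool)
    lat_b = np.zeros((ny, nx), dtype=bool)

    if spec.cargo_density > 0 and spec.category_probs is not None:
        cats = rng.choice(4, size=n, p=np.asarray(spec.category_probs, dtype=float))
        for k in range(n):
            in_stack = lab2d == k + 1
            stack_pids = np.unique(pid[in_stack])
            want_a = cats[k] in (0, 1)
            want_b = cats[k] in (0, 2)
            for want, lat in ((want_a, lat_a), (want_b, lat_b)):
                chosen = stack_pids[rng.random(stack_pids.size) < spec.cargo_density]
                if want and chosen.size == 0:
                    chosen = np.array([rng.choice(stack_pids)])
                if want:
                    lat |= in_stack & np.isin(pid, chosen)
            contains_a[k] = want_a
            contains_b[k] = want_b
    elif spec.cargo_density > 0:
        sel_a, sel_b = _assign_subdomains(pid[disk_any], rng, spec.mixing, spec.cargo_density)
        lat_a = disk_any & np.isin(pid, sel_a)
        lat_b = disk_any & np.isin(pid, sel_b)
        for k in range(n):
            in_stack = lab2d == k + 1
            contains_a[k] = bool((lat_a & in_stack).any())
            contains_b[k] = bool((lat_b & in_stack).any())

    zwin_c = _layer_window(zc, base + spec.cargo_offset_nm, spec.layer_thickness_nm)
    channels[CARGO_A] = zwin_c[:, None, None] & lat_a[None]
    channels[CARGO_B] = zwin_c[:, None, None] & lat_b[None]

    cat_names = np.where(
        contains_a & contains_b,
        "both",
        np.where(contains_a, "A_only", np.where(contains_b, "B_only", "neither")),
    )
    table = pd.DataFrame(
        {
            "stack_id": np.arange(1, n + 1),
            "center_y_nm": centers[:, 0],
            "center_x_nm": centers[:, 1],
            "contains_a": contains_a,
            "contains_b": contains_b,
            "category": cat_names,
        }
    )
    return channels, labels3d, table


def _build_er(spec: SceneSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    nz, ny, nx = spec.grid_shape
    h = spec.fine_grid_step_nm
    fz, fy, fx = spec.field_size_nm
    skel = np.zeros((nz, ny, nx), dtype=bool)
    margin = spec.er_tubule_radius_nm + 2 * h
    seg_len = 250.0
    n_segments = 24
    for _ in range(spec.er_n_tubules):
        pos = rng.uniform(
            [margin, margin, margin], [fz - margin, fy - margin, fx - margin]
        )
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        for _ in range(n_segments):
            direction = direction + 0.6 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            end = pos + direction * seg_len
            # reflect at the walls
            for ax, ext in enumerate((fz, fy, fx)):
                if end[ax] < margin or end[ax] > ext - margin:
                    direction[ax] *= -1.0
                    end = pos + direction * seg_len
            ts = np.linspace(0.0, 1.0, max(2, int(seg_len / h) + 1))
            pts = pos[None, :] + ts[:, None] * (end - pos)[None, :]
            idx = np.clip(
                (pts / h).astype(int), 0, np.array([nz, ny, nx]) - 1
            )
            skel[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            pos = end
    dist = ndimage.distance_transform_edt(~skel, sampling=(h, h, h))
    network = dist <= spec.er_tubule_radius_nm

    channels: dict[str, np.ndarray] = {"er": network}
    if spec.cargo_density > 0:
        zi, yi, xi = np.nonzero(network)
        s = max(1, int(round(spec.subdomain_scale_nm / h)))
        kx = nx // s + 2
        ky = ny // s + 2
        pid_vals = (zi // s) * (ky * kx) + (yi // s) * kx + (xi // s)
        sel_a, sel_b = _assign_subdomains(pid_vals, rng, spec.mixing, spec.cargo_density)
        a = np.zeros_like(network)
        b = np.zeros_like(network)
        in_a = np.isin(pid_vals, sel_a)
        in_b = np.isin(pid_vals, sel_b)
        a[zi[in_a], yi[in_a], xi[in_a]] = True
        b[zi[in_b], yi[in_b], xi[in_b]] = True
        channels[CARGO_A] = a
        channels[CARGO_B] = b
    else:
        channels[CARGO_A] = np.zeros_like(network)
        channels[CARGO_B] = np.zeros_like(network)
    return channels


def _build_beads(spec: SceneSpec, rng: np.random.Generator):
    nz, ny, nx = spec.grid_shape
    h = spec.fine_grid_step_nm
    fz, fy, fx = spec.field_size_nm
    radius = spec.beads.diameter_nm / 2.0
    margin = max(radius + 2 * h, 500.0)
    pts = _place_points_2d(
        spec.beads.count,
        (margin, margin),
        (fy - margin, fx - margin),
        spec.beads.min_separation_nm,
        rng,
        spec.placement_retries,
    )
    occ = np.zeros((nz, ny, nx), dtype=bool)
    centers = np.column_stack([np.full(len(pts), fz / 2.0), pts])
    for c in centers:
        _paint_sphere(occ, c, radius, h)
    return {"beads": occ}, centers


# ---------------------------------------------------------------------------
# public API


def build_scene(spec: SceneSpec, seed: Optional[int] = None) -> GroundTruth:
    """Build the ground-truth occupancy fields for a scene.

    Deterministic given ``(spec, seed)``; ``seed`` defaults to ``spec.seed``.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)

    ministack_labels = None
    ministack_table = None
    bead_centers = None

    if spec.mode == "ribbon":
        channels = _build_ribbon(spec, rng)
    elif spec.mode == "ministacks":
        channels, ministack_labels, ministack_table = _build_ministacks(spec, rng)
    elif spec.mode in ("er_bfa", "er_rush"):
        channels = _build_er(spec, rng)
    elif spec.mode == "beads":
        channels, bead_centers = _build_beads(spec, rng)
    else:  # pragma: no cover - validate() already rejects this
        raise SceneValidationError(spec.mode)

    if spec.mode != "beads" and spec.organelles.count > 0:
        occ = np.zeros(spec.grid_shape, dtype=bool)
        r = spec.organelles.radius_nm
        fz, fy, fx = spec.field_size_nm
        for _ in range(spec.organelles.count):
            c = rng.uniform([r, r, r], [fz - r, fy - r, fx - r])
            _paint_sphere(occ, c, r, spec.fine_grid_step_nm)
        channels[ORGANELLE] = occ

    gt = GroundTruth(
        channels={k: np.ascontiguousarray(v) for k, v in channels.items()},
        spec=spec,
        seed=seed,
        ministack_labels=ministack_labels,
        ministack_table=ministack_table,
        bead_centers_nm=bead_centers,
    )
    gt.empty_channels = {k for k, v in gt.channels.items() if not v.any()}
    if CARGO_A in gt.channels and CARGO_B in gt.channels:
        gt.true_overlap = true_overlap_fractions(gt, CARGO_A, CARGO_B)
    return gt


def true_overlap_fractions(gt: GroundTruth, a: str, b: str) -> tuple[float, float]:
    """Ground-truth overlap fractions (|A∩B|/|A|, |A∩B|/|B|) on the fine grid.

    Returns (0.0, 0.0) when a channel is empty; the channel is then recorded
    in ``gt.empty_channels``.
    """
    for name in (a, b):
        if name not in gt.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(gt.channels)}")
    fa = gt.channels[a]
    fb = gt.channels[b]
    na = int(fa.sum())
    nb = int(fb.sum())
    nab = int((fa & fb).sum())
    frac_a = nab / na if na else 0.0
    frac_b = nab / nb if nb else 0.0
    if na == 0:
        gt.empty_channels.add(a)
    if nb == 0:
        gt.empty_channels.add(b)
    return (frac_a, frac_b)


def ministack_truth_categories(gt: GroundTruth) -> pd.DataFrame:
    """Recompute per-ministack cargo categories by direct voxel counting on
    the fine grid (independent check of the bookkeeping recorded at
    generation time)."""
    if gt.ministack_labels is None:
        raise ValueError("not a ministacks scene")
    labels = gt.ministack_labels
    n = int(labels.max())
    rows = []
    for k in range(1, n + 1):
        in_stack = labels == k
        has_a = bool((gt.channels[CARGO_A] & in_stack).any())
        has_b = bool((gt.channels[CARGO_B] & in_stack).any())
        cat = (
            "both"
            if has_a and has_b
            else "A_only" if has_a else "B_only" if has_b else "neither"
        )
        rows.append({"stack_id": k, "contains_a": has_a, "contains_b": has_b, "category": cat})
    return pd.DataFrame(rows)
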