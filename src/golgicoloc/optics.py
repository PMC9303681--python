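"""Forward imaging model: Gaussian PSF, blurring, voxel integration, noise.

The microscope is modelled as a shift-invariant anisotropic Gaussian PSF
(sigma = FWHM / (2 sqrt(2 ln 2)) per axis).  Rendering blurs the fine-grid
occupancy with the analytic Gaussian, integrates photons onto the acquisition
voxel grid by block summation (photon conserving, no interpolation), scales
by ``gain`` (expected photons per occupied fine voxel), adds a flat
``background``, and finally applies Poisson shot noise plus additive Gaussian
read noise clipped at zero.

Default acquisition geometry mirrors a super-resolution Airyscan-style
acquisition: 35 nm lateral pixels, 159 nm z-step, with raw lateral FWHM
around 150 nm.

Axis order is (channel, z, y, x); voxel-size tuples are (z, y, x) in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .scenes import GroundTruth, SceneSpec, build_scene

__all__ = [
    "FWHM_TO_SIGMA",
    "DEFAULT_VOXEL_NM",
    "PSFVolume",
    "ImageStack",
    "make_psf",
    "render",
    "render_expected",
    "add_noise",
    "render_bead_field",
]

#: sigma = FWHM * FWHM_TO_SIGMA for a Gaussian profile
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: acquisition voxel (z, y, x) in nm: 0.159 um z-step, 35 nm pixels
DEFAULT_VOXEL_NM: tuple[float, float, float] = (159.0, 35.0, 35.0)

DEFAULT_FWHM_LATERAL_NM = 150.0
DEFAULT_FWHM_AXIAL_NM = 400.0


@dataclass(frozen=True)
class PSFVolume:
    """Separable Gaussian point-spread function sampled on the acquisition
    voxel grid (unit sum), with the generating FWHMs recorded."""

    kernel: np.ndarray
    fwhm_lateral_nm: float
    fwhm_axial_nm: float
    voxel_nm: tuple[float, float, float]

    @property
    def sigmas_nm(self) -> tuple[float, float, float]:
        return (
            self.fwhm_axial_nm * FWHM_TO_SIGMA,
            self.fwhm_lateral_nm * FWHM_TO_SIGMA,
            self.fwhm_lateral_nm * FWHM_TO_SIGMA,
        )


@dataclass
class ImageStack:
    """Multi-channel 3D stack with anisotropic voxel sizes.

    ``data`` has shape (channel, z, y, x); intensities are non-negative.
    """

    data: np.ndarray
    voxel_nm: tuple[float, float, float]
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must be (channel, z, y, x)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data")
        if any(v <= 0 for v in self.voxel_nm):
            raise ValueError("voxel sizes must be positive")

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")
        return self.data[i]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def make_psf(
    fwhm_lateral_nm: float,
    fwhm_axial_nm: float,
    voxel_nm: Sequence[float] = DEFAULT_VOXEL_NM,
) -> PSFVolume:
    """Build a separable anisotropic Gaussian PSF kernel.

    The kernel is truncated at >= 1.5 FWHM half-extent per axis (so the full
    extent covers at least 3 FWHM) and renormalized to unit sum.  A FWHM of
    exactly 0 requests a single-voxel delta along that axis.
    """
    if fwhm_lateral_nm < 0 or fwhm_axial_nm < 0:
        raise ValueError("FWHM must be >= 0")
    voxel_nm = tuple(float(v) for v in voxel_nm)
    fwhms = (fwhm_axial_nm, fwhm_lateral_nm, fwhm_lateral_nm)
    profiles = []
    for fwhm, vox in zip(fwhms, voxel_nm):
        if fwhm == 0:
            profiles.append(np.ones(1))
            continue
        sigma = fwhm * FWHM_TO_SIGMA
        r = int(np.ceil(1.5 * fwhm / vox))
        x = np.arange(-r, r + 1) * vox
        profiles.append(np.exp(-0.5 * (x / sigma) ** 2))
    kernel = (
        profiles[0][:, None, None]
        * profiles[1][None, :, None]
        * profiles[2][None, None, :]
    )
    kernel /= kernel.sum()
    return PSFVolume(
        kernel=kernel,
        fwhm_lateral_nm=float(fwhm_lateral_nm),
        fwhm_axial_nm=float(fwhm_axial_nm),
        voxel_nm=voxel_nm,
    )


# ---------------------------------------------------------------------------
# blurring and voxel integration


def _bbox_with_margin(occ: np.ndarray, margins: Sequence[int]):
    slices = []
    for ax, m in enumerate(margins):
        proj = occ.any(axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        if nz.size == 0:
            return None
        slices.append(slice(max(0, nz[0] - m), min(occ.shape[ax], nz[-1] + 1 + m)))
    return tuple(slices)


def _blur_fine(occ: np.ndarray, sigmas_nm, step: float) -> np.ndarray:
    """Gaussian-blur a binary occupancy field (float32, truncate at 4 sigma).

    The blur is restricted to occupied bounding boxes plus a 4-sigma margin
    and embedded back, which is exact to the truncation tolerance.  For
    fields made of many small connected components (dispersed stacks,
    organelles, beads) each component is blurred in its own box and the
    contributions are summed — exact by linearity, since components are
    disjoint.
    """
    sig_vox = [s / step for s in sigmas_nm]
    out = np.zeros(occ.shape, dtype=np.float32)
    margins = [int(np.ceil(4 * s)) + 1 for s in sig_vox]

    def blur_into(box, sub):
        if all(s == 0 for s in sig_vox):
            out[box] += sub
        else:
            out[box] += ndimage.gaussian_filter(sub, sigma=sig_vox, truncate=4.0)

    # decompose by connected components of the lateral projection: disjoint
    # in projection implies disjoint in 3D, so summing the blurs is exact
    proj = occ.any(axis=0)
    lbl2d, n = ndimage.label(proj, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return out
    if n > 1:
        boxes2d = ndimage.find_objects(lbl2d)
        total = 0
        plans = []
        for k, (oy, ox) in enumerate(boxes2d, start=1):
            zs = np.nonzero(occ[:, oy, ox].any(axis=(1, 2)))[0]
            core = (slice(zs[0], zs[-1] + 1), oy, ox)
            box = tuple(
                slice(max(0, sl.start - m), min(dim, sl.stop + m))
                for sl, m, dim in zip(core, margins, occ.shape)
            )
            plans.append((k, core, box))
            total += np.prod([s.stop - s.start for s in box])
        if total < occ.size // 2:
            for k, core, box in plans:
                sub = np.zeros(tuple(s.stop - s.start for s in box), dtype=np.float32)
                inner = tuple(
                    slice(c.start - b.start, c.stop - b.start)
                    for c, b in zip(core, box)
                )
                sub[inner] = occ[core] & (lbl2d[core[1], core[2]] == k)
                blur_into(box, sub)
            return out
    box = _bbox_with_margin(occ, margins)
    blur_into(box, occ[box].astype(np.float32))
    return out


def _bin_axis(arr: np.ndarray, axis: int, step: float, voxel: float) -> np.ndarray:
    """Sum fine voxels into acquisition voxels along one axis (block
    integration by assignment of fine-voxel centers)."""
    n_fine = arr.shape[axis]
    extent = n_fine * step
    n = max(1, int(round(extent / voxel)))
    centers = (np.arange(n_fine) + 0.5) * step
    idx = np.floor(centers / voxel).astype(np.intp)
    keep = idx < n
    if not keep.all():
        arr = np.take(arr, np.nonzero(keep)[0], axis=axis)
        idx = idx[keep]
    starts = np.searchsorted(idx, np.arange(n))
    return np.add.reduceat(arr, starts, axis=axis)


def bin_to_voxels(fine: np.ndarray, step: float, voxel_nm: Sequence[float]) -> np.ndarray:
    """Integrate a fine-grid field onto the acquisition voxel grid."""
    out = fine
    for ax in range(3):
        out = _bin_axis(out, ax, step, float(voxel_nm[ax]))
    return out


def _forward_channel(
    occ: np.ndarray, sigmas_nm, step: float, voxel_nm
) -> np.ndarray:
    """Blur occupancy with the Gaussian PSF and integrate onto the voxel grid.

    Separable Gaussian passes commute with block integration along the other
    axes, so the axial blur is applied after lateral binning (identical
    result, far cheaper on large fields).
    """
    lateral = _blur_fine(occ, (0.0, sigmas_nm[1], sigmas_nm[2]), step)
    part = _bin_axis(_bin_axis(lateral, 1, step, float(voxel_nm[1])), 2, step, float(voxel_nm[2]))
    if sigmas_nm[0] > 0:
        part = ndimage.gaussian_filter1d(part, sigmas_nm[0] / step, axis=0, truncate=4.0)
    return _bin_axis(part, 0, step, float(voxel_nm[0]))


def render_expected(
    gt: GroundTruth,
    psf: PSFVolume,
    gain: float,
    background: float = 0.0,
    channels: Optional[Sequence[str]] = None,
) -> ImageStack:
    """Noiseless forward model: expected photon counts per acquisition voxel.

    Each occupied fine voxel emits ``gain`` expected photons, spread by the
    Gaussian PSF and integrated onto the acquisition grid defined by
    ``psf.voxel_nm``; ``background`` photons are added per voxel.
    """
    if gain < 0 or background < 0:
        raise ValueError("gain and background must be non-negative")
    step = gt.fine_step_nm
    if step > min(psf.voxel_nm) / 3.0:
        raise ValueError(
            f"fine grid step {step} nm must oversample the acquisition voxel "
            f"{min(psf.voxel_nm)} nm by at least 3x"
        )
    names = list(channels) if channels is not None else list(gt.channels)
    planes = []
    for name in names:
        occ = gt.channels[name]
        signal = _forward_channel(occ, psf.sigmas_nm, step, psf.voxel_nm)
        planes.append((gain * signal + background).astype(np.float64))
    data = np.stack(planes, axis=0)
    meta = {
        "gain": float(gain),
        "background": float(background),
        "noiseless": True,
        "psf_fwhm_lateral_nm": psf.fwhm_lateral_nm,
        "psf_fwhm_axial_nm": psf.fwhm_axial_nm,
        "scene_seed": gt.seed,
    }
    return ImageStack(data=data, voxel_nm=psf.voxel_nm, channel_names=names, meta=meta)


def add_noise(stack: ImageStack, read_noise_sd: float = 0.0, seed: int = 0) -> ImageStack:
    """Poisson shot noise plus Gaussian read noise, clipped at zero.

    Deterministic given ``seed``; the input stack holds expected counts.
    """
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(stack.data).astype(np.float64)
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)
    meta = dict(stack.meta)
    meta.update(noiseless=False, read_noise_sd=float(read_noise_sd), noise_seed=int(seed))
    return ImageStack(
        data=noisy,
        voxel_nm=stack.voxel_nm,
        channel_names=list(stack.channel_names),
        meta=meta,
    )


def render(
    gt: GroundTruth,
    psf: PSFVolume,
    gain: float,
    background: float = 0.0,
    read_noise_sd: float = 0.0,
    seed: int = 0,
    channels: Optional[Sequence[str]] = None,
    noiseless: bool = False,
) -> ImageStack:
    """Full forward model; see :func:`render_expected` and :func:`add_noise`."""
    expected = render_expected(gt, psf, gain, background, channels)
    if noiseless:
        return expected
    return add_noise(expected, read_noise_sd=read_noise_sd, seed=seed)


def render_bead_field(
    spec: SceneSpec,
    psf: PSFVolume,
    gain: float,
    seed: int = 0,
    background: float = 0.0,
    read_noise_sd: float = 0.0,
    noiseless: bool = False,
) -> ImageStack:
    """Render a calibration-bead scene; true bead centers are recorded in
    ``meta['bead_centers_nm']`` (z, y, x)."""
    if spec.mode != "beads":
        raise ValueError("render_bead_field requires a beads-mode SceneSpec")
    gt = build_scene(spec, seed=seed)
    stack = render(
        gt,
        psf,
        gain,
        background=background,
        read_noise_sd=read_noise_sd,
        seed=seed + 1,
        noiseless=noiseless,
    )
    stack.meta["bead_centers_nm"] = np.asarray(gt.bead_centers_nm)
    return stack
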