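"""Calibration-control experiments that validate the pipeline end to end.

These are the synthetic analogues of the control measurements that anchor
the colocalization scale:

* dual-label control — the same rendered channel analysed against an exact
  copy of itself must give coefficients of exactly 1.
* perfect-colocalization control — two independently noised acquisitions of
  the same underlying structure (the synthetic analogue of staining one
  protein with two antibodies) must give a cohort mean coefficient near 1.
* chance-overlap control — two spatially independent organelle structures in
  the same cell (a compact Golgi ribbon versus dispersed lysosome-like
  spheres) must give a negligible cohort mean coefficient.
* mixing recovery — the measured coefficient must increase monotonically
  with the generator's subdomain mixing parameter phi.

Cohort sizes and cell geometry are desk-scale choices (see the methods
note); all randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .coloc import coloc_coefficients, full_domain_region, make_region_mask
from .config import child_seed
from .optics import ImageStack, add_noise, make_psf, render, render_expected
from .restoration import richardson_lucy
from .scenes import OrganelleSpec, SceneSpec, build_scene
from .segmentation import SegmentationParams, segment_channel
from .stats import CohortSummary, aggregate_cells

__all__ = [
    "dual_label_control",
    "perfect_coloc_cohort",
    "chance_coloc_cohort",
    "mixing_recovery",
]

_PSF = dict(fwhm_lateral_nm=150.0, fwhm_axial_nm=400.0)

#: imaged field of a whole-cell acquisition (9 z-sections), nm
_CELL_FIELD = (1431.0, 10000.0, 10000.0)
#: imaged field of a Golgi-region acquisition, nm
_GOLGI_FIELD = (1431.0, 6000.0, 6000.0)


def dual_label_control(seed: int = 0):
    """Channel-versus-itself coefficient (exact dual-label control).

    Renders one noisy Golgi marker channel, duplicates it as a second
    channel, segments both and computes the full-domain coefficients.
    """
    spec = SceneSpec(mode="ribbon", field_size_nm=_GOLGI_FIELD)
    gt = build_scene(spec, seed=child_seed(seed, 0))
    psf = make_psf(**_PSF)
    stack = render(
        gt, psf, gain=4.0, background=2.0, read_noise_sd=2.0,
        seed=child_seed(seed, 1), channels=["trans"],
    )
    dup = ImageStack(
        np.concatenate([stack.data, stack.data.copy()]),
        stack.voxel_nm,
        ["marker", "marker_copy"],
    )
    params = SegmentationParams()
    a = segment_channel(dup, "marker", params)
    b = segment_channel(dup, "marker_copy", params)
    return coloc_coefficients(a, b, full_domain_region(a.mask.shape))


def perfect_coloc_cohort(
    n_cells: int = 20,
    seed: int = 0,
    peak_photons: float = 400.0,
    background: float = 5.0,
    read_noise_sd: float = 3.0,
    rl_iterations: int = 30,
) -> CohortSummary:
    """Perfect-colocalization calibration control.

    Each cell renders the same ground-truth marker structure twice with
    independent Poisson + read noise at high SNR, deconvolves and segments
    both acquisitions, and reports coefficient 1; the cohort mean is the
    recovered "perfect" level.
    """
    psf = make_psf(**_PSF)
    params = SegmentationParams()
    vals = []
    for i in range(n_cells):
        spec = SceneSpec(mode="ribbon", field_size_nm=_GOLGI_FIELD)
        gt = build_scene(spec, seed=child_seed(seed, i, 0))
        expected = render_expected(gt, psf, gain=1.0, channels=["trans"])
        expected.data = expected.data * (peak_photons / expected.data.max()) + background
        n1 = add_noise(expected, read_noise_sd, seed=child_seed(seed, i, 1))
        n2 = add_noise(expected, read_noise_sd, seed=child_seed(seed, i, 2))
        pair = ImageStack(
            np.concatenate([n1.data, n2.data]), expected.voxel_nm, ["rep1", "rep2"]
        )
        dec = richardson_lucy(pair, psf, rl_iterations)
        a = segment_channel(dec, "rep1", params)
        b = segment_channel(dec, "rep2", params)
        vals.append(coloc_coefficients(a, b).coefficient1)
    return aggregate_cells(vals, label="perfect_control")


def chance_coloc_cohort(
    n_cells: int = 20,
    seed: int = 0,
    n_lysosomes: int = 40,
    lysosome_radius_nm: float = 250.0,
    rl_iterations: int = 30,
) -> CohortSummary:
    """Chance-overlap (negligible) control.

    Each cell holds a compact Golgi ribbon plus ``n_lysosomes`` spheres
    placed uniformly at random, independent of the Golgi; the coefficient of
    the Golgi channel over the lysosome channel measures chance coincidence.
    """
    psf = make_psf(**_PSF)
    params = SegmentationParams()
    vals = []
    for i in range(n_cells):
        spec = SceneSpec(
            mode="ribbon",
            field_size_nm=_CELL_FIELD,
            organelles=OrganelleSpec(count=n_lysosomes, radius_nm=lysosome_radius_nm),
        )
        gt = build_scene(spec, seed=child_seed(seed, i, 0))
        stack = render(
            gt, psf, gain=4.0, background=2.0, read_noise_sd=2.0,
            seed=child_seed(seed, i, 1), channels=["trans", "organelle"],
        )
        dec = richardson_lucy(stack, psf, rl_iterations)
        golgi = segment_channel(dec, "trans", params)
        lyso = segment_channel(dec, "organelle", params)
        vals.append(coloc_coefficients(golgi, lyso).coefficient1)
    return aggregate_cells(vals, label="chance_control")


def mixing_recovery(
    phis: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_cells: int = 20,
    seed: int = 0,
    rl_iterations: int = 30,
) -> dict[float, CohortSummary]:
    """Mean recovered coefficient 1 per mixing level phi.

    Noiseless renders of compact ribbon scenes run through the full
    measurement chain (deconvolution, segmentation, trans-marker region
    mask); used to check that the measured coefficient increases
    monotonically with the generated cargo mixing.  Deconvolution matters
    here: without it the blurred edges of adjacent exclusive subdomains
    cross the threshold together and inflate the phi = 0 baseline.
    """
    psf = make_psf(**_PSF)
    params = SegmentationParams()
    out: dict[float, CohortSummary] = {}
    for phi in phis:
        vals = []
        for i in range(n_cells):
            spec = SceneSpec(
                mode="ribbon",
                field_size_nm=(1431.0, 3600.0, 3600.0),
                ribbon_radius_nm=1100.0,
                ribbon_width_nm=500.0,
                mixing=phi,
            )
            gt = build_scene(spec, seed=child_seed(seed, int(phi * 100), i))
            stack = render(
                gt, psf, gain=4.0, noiseless=True,
                channels=["trans", "cargoA", "cargoB"],
            )
            dec = richardson_lucy(stack, psf, rl_iterations)
            surf = {n: segment_channel(dec, n, params) for n in dec.channel_names}
            region = make_region_mask([surf["trans"]], "TGN")
            vals.append(
                coloc_coefficients(surf["cargoA"], surf["cargoB"], region).coefficient1
            )
        out[phi] = aggregate_cells(vals, label=f"phi={phi}")
    return out
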