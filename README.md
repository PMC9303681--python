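# golgicoloc

Object-based 3D colocalization of Golgi cargo proteins, with a synthetic
super-resolution microscope to validate every step of the measurement.

## The problem

Deciding whether two membrane proteins — for example the protease BACE1 and
its substrate APP — share a Golgi sub-compartment requires measuring their
spatial overlap at a resolution (~90–150 nm laterally) where segmentation,
deconvolution and thresholding choices can make or break the answer.  Raw
cell images for such studies are rarely deposited, and the commercial
processing chain (Huygens deconvolution, Imaris surface–surface
colocalization) is a black box.  `golgicoloc` re-implements the
quantification as an open, tested pipeline and couples it to a scene
generator with exact voxel-level ground truth, so the whole measurement can
be validated by parameter recovery.

## The statistic

For segmented binary volumes A and B restricted to a marker-defined region
mask R (e.g. "TGN" = union of two trans-Golgi marker channels):

```
coefficient 1 = V(A ∩ B ∩ R) / V(A ∩ R)        (A-over-B)
coefficient 2 = V(A ∩ B ∩ R) / V(B ∩ R)        (B-over-A)
```

where V(·) is a voxel count — directional Manders-style volume
coefficients.  They are read against calibration bands derived from control
marker pairs: **negligible** (cis- vs trans-Golgi markers, chance level
≈ 0.19), **moderate** (two distinct trans-Golgi markers, ≈ 0.55), and
**perfect** (one protein stained with two antibodies, ≈ 0.995).

The pipeline stages: synthetic scene → Gaussian-PSF rendering with
Poisson + read noise onto a 35/35/159 nm voxel grid → Richardson–Lucy
deconvolution → background-subtracted Otsu segmentation → region mask →
coefficients, plus per-ministack cargo co-occurrence (both / A-only /
B-only / neither) for nocodazole-style dispersed-Golgi scenes, bead-based
FWHM resolution reports, linescans, and cohort statistics (mean ± SEM,
Welch t-tests).  See `docs/methods.md` for the full model description.

## Worked example

```python
import golgicoloc as g

# a Golgi ribbon whose two cargoes are fully segregated (mixing phi = 0)
spec = g.SceneSpec(mode="ribbon", field_size_nm=(1431., 6000., 6000.), mixing=0.0)
gt = g.build_scene(spec, seed=2)
print("true overlap:", gt.true_overlap)

psf = g.make_psf(fwhm_lateral_nm=150., fwhm_axial_nm=400.)
stack = g.render(gt, psf, gain=4.0, background=2.0, read_noise_sd=2.0, seed=7,
                 channels=["trans", "cargoA", "cargoB"])
dec = g.richardson_lucy(stack, psf, iterations=30)

surf = {n: g.segment_channel(dec, n) for n in stack.channel_names}
region = g.make_region_mask([surf["trans"]], "TGN")
res = g.coloc_coefficients(surf["cargoA"], surf["cargoB"], region)
print(f"coefficient1={res.coefficient1:.3f} coefficient2={res.coefficient2:.3f}")
print("class:", g.classify_coefficient(res.coefficient1, g.reference_bands()))
```

prints

```
true overlap: (0.0, 0.0)
coefficient1=0.017 coefficient2=0.029
class: negligible
```

— the generator placed the two cargoes in disjoint membrane subdomains
(true overlap 0), and the full imaging + analysis chain recovers
coefficients of ~0.02, correctly classified as negligible (chance-level)
colocalization.  Re-running with `mixing=1.0` yields coefficient1 = 0.983
and class `high`.

The same analysis is available from the shell:

```
golgicoloc run --config config.yaml      # simulate → … → report
golgicoloc coloc image.ome.tif --a cargoA --b cargoB --region trans --out coloc.csv
golgicoloc resolution --beads beads.ome.tif --out fwhm.csv
```

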