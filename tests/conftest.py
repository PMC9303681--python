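import numpy as np
import pytest

from golgicoloc import SceneSpec, build_scene, make_psf
from golgicoloc.scenes import BeadSpec


@pytest.fixture(scope="session")
def small_ribbon_spec():
    """A compact ribbon scene cheap enough for many unit tests."""
    return SceneSpec(
        mode="ribbon",
        field_size_nm=(1431.0, 3000.0, 3000.0),
        ribbon_radius_nm=900.0,
        ribbon_span_deg=140.0,
        ribbon_width_nm=400.0,
        mixing=0.5,
    )


@pytest.fixture(scope="session")
def small_ribbon(small_ribbon_spec):
    return build_scene(small_ribbon_spec, seed=11)


@pytest.fixture(scope="session")
def default_psf():
    return make_psf(150.0, 400.0)


@pytest.fixture(scope="session")
def bead_spec():
    return SceneSpec(
        mode="beads",
        field_size_nm=(1431.0, 5000.0, 5000.0),
        beads=BeadSpec(count=8, diameter_nm=100.0, min_separation_nm=900.0),
    )


def brute_force_overlap(a: np.ndarray, b: np.ndarray, region=None):
    """Triple-loop oracle for the volume colocalization counts."""
    if region is None:
        region = np.ones_like(a, dtype=bool)
    va = vb = vab = 0
    nz, ny, nx = a.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not region[z, y, x]:
                    continue
                ia = bool(a[z, y, x])
                ib = bool(b[z, y, x])
                va += ia
                vb += ib
                vab += ia and ib
    return va, vb, vab
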