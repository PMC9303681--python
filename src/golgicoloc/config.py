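"""Run configuration: YAML/JSON parsing into typed parameter objects.

All physical quantities in configs are nm; image files carry um metadata
(the conversion is localized in :mod:`golgicoloc.io`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .optics import DEFAULT_FWHM_AXIAL_NM, DEFAULT_FWHM_LATERAL_NM, DEFAULT_VOXEL_NM
from .restoration import DEFAULT_RL_ITERATIONS
from .scenes import BeadSpec, OrganelleSpec, SceneSpec
from .segmentation import SegmentationParams

__all__ = [
    "OpticsParams",
    "RestorationParams",
    "ColocPair",
    "MinistackParams",
    "RunConfig",
    "load_config",
    "config_to_dict",
    "scene_spec_from_dict",
    "child_seed",
]


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31.

    Children are derived by fixed arithmetic from (master seed, key), so a
    cohort can be extended without reshuffling existing cells.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class OpticsParams:
    fwhm_lateral_nm: float = DEFAULT_FWHM_LATERAL_NM
    fwhm_axial_nm: float = DEFAULT_FWHM_AXIAL_NM
    voxel_nm: tuple[float, float, float] = DEFAULT_VOXEL_NM
    gain: float = 4.0
    background: float = 2.0
    read_noise_sd: float = 2.0
    noiseless: bool = False


@dataclass(frozen=True)
class RestorationParams:
    enabled: bool = True
    iterations: int = DEFAULT_RL_ITERATIONS


@dataclass(frozen=True)
class ColocPair:
    a: str = "cargoA"
    b: str = "cargoB"
    region_markers: tuple[str, ...] = ()  # empty -> full domain
    region_label: str = "full"


@dataclass(frozen=True)
class MinistackParams:
    enabled: Optional[bool] = None  # None = auto (on for ministacks scenes)
    presence_min: int = 2
    region_markers: tuple[str, ...] = ()  # empty -> all cisternal markers
    min_component_voxels: int = 4


@dataclass(frozen=True)
class RunConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    optics: OpticsParams = field(default_factory=OpticsParams)
    restoration: RestorationParams = field(default_factory=RestorationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    coloc: ColocPair = field(default_factory=ColocPair)
    ministacks: MinistackParams = field(default_factory=MinistackParams)
    n_cells: int = 1
    seed: int = 0
    output_dir: str = "golgicoloc_run"
    write_images: bool = False

    def validate(self) -> None:
        self.scene.validate()
        self.segmentation.validate(self.optics.voxel_nm)
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def scene_spec_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    if "organelles" in d and isinstance(d["organelles"], dict):
        d["organelles"] = OrganelleSpec(**d["organelles"])
    if "beads" in d and isinstance(d["beads"], dict):
        d["beads"] = BeadSpec(**d["beads"])
    for key in ("field_size_nm", "category_probs"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SceneSpec(**d)


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def config_from_dict(d: dict) -> RunConfig:
    kwargs: dict = {
        k: d[k]
        for k in ("n_cells", "seed", "output_dir", "write_images")
        if k in d
    }
    if "scene" in d:
        kwargs["scene"] = scene_spec_from_dict(d["scene"])
    if "optics" in d:
        kwargs["optics"] = OpticsParams(**_tupled(d["optics"], "voxel_nm"))
    if "restoration" in d:
        kwargs["restoration"] = RestorationParams(**d["restoration"])
    if "segmentation" in d:
        kwargs["segmentation"] = SegmentationParams(**d["segmentation"])
    if "coloc" in d:
        kwargs["coloc"] = ColocPair(**_tupled(d["coloc"], "region_markers"))
    if "ministacks" in d:
        kwargs["ministacks"] = MinistackParams(**_tupled(d["ministacks"], "region_markers"))
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data or {})


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
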