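"""Reading/writing images, tables and run manifests.

Images are OME-TIFF (axes CZYX) with PhysicalSizeX/Y/Z voxel metadata in um
(the rest of the package works in nm; the unit conversion lives here).  A
JSON sidecar carries acquisition metadata (gain, noise parameters, seeds,
channel names).  Tables are CSV (coefficients printed with 4 decimals) and
JSON (full precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .coloc import ColocResult
from .ministacks import MinistackTable
from .optics import ImageStack
from .stats import CohortSummary

__all__ = [
    "write_ome_tiff",
    "read_ome_tiff",
    "write_ground_truth",
    "write_coloc_csv",
    "write_ministack_outputs",
    "write_cohort_json",
    "write_manifest",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, set):
            return sorted(obj)
        return super().default(obj)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_ome_tiff(stack: ImageStack, path) -> Path:
    """Write an ImageStack as OME-TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    vz, vy, vx = stack.voxel_nm
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz / 1000.0,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )
    sidecar = {
        "voxel_nm": list(stack.voxel_nm),
        "channel_names": list(stack.channel_names),
        "meta": stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, cls=_NumpyEncoder))
    return path


def read_ome_tiff(path) -> ImageStack:
    """Read an OME-TIFF written by :func:`write_ome_tiff` (the JSON sidecar,
    when present, supplies voxel sizes and metadata; otherwise they are
    parsed from the OME-XML)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        return ImageStack(
            data=data,
            voxel_nm=tuple(info["voxel_nm"]),
            channel_names=list(info["channel_names"]),
            meta=info.get("meta", {}),
        )
    with tifffile.TiffFile(path) as tf:
        ome = tifffile.xml2dict(tf.ome_metadata) if tf.ome_metadata else {}
    pix = ome.get("OME", {}).get("Image", {})
    if isinstance(pix, list):
        pix = pix[0]
    pix = pix.get("Pixels", {})
    voxel_nm = (
        float(pix.get("PhysicalSizeZ", 0.159)) * 1000.0,
        float(pix.get("PhysicalSizeY", 0.035)) * 1000.0,
        float(pix.get("PhysicalSizeX", 0.035)) * 1000.0,
    )
    chans = pix.get("Channel", [])
    if isinstance(chans, dict):
        chans = [chans]
    names = [c.get("Name", f"ch{i}") for i, c in enumerate(chans)] or [
        f"ch{i}" for i in range(data.shape[0])
    ]
    return ImageStack(data=data, voxel_nm=voxel_nm, channel_names=names, meta={})


def write_ground_truth(gt, path) -> Path:
    """Export a GroundTruth as a binary multi-channel OME-TIFF on the fine
    grid, with a JSON sidecar holding the scene spec, seed and true overlap."""
    import dataclasses as dc

    path = Path(path)
    names = list(gt.channels)
    data = np.stack([gt.channels[n] for n in names]).astype(np.uint8)
    h = gt.fine_step_nm
    stack = ImageStack(
        data=data,
        voxel_nm=(h, h, h),
        channel_names=names,
        meta={
            "ground_truth": True,
            "seed": gt.seed,
            "true_overlap": gt.true_overlap,
            "empty_channels": sorted(gt.empty_channels),
            "scene_spec": dc.asdict(gt.spec),
        },
    )
    return write_ome_tiff(stack, path)


def coloc_results_frame(results: Sequence[ColocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "region": [r.region for r in results],
            "channel_a": [r.channel_a for r in results],
            "channel_b": [r.channel_b for r in results],
            "coefficient1": [r.coefficient1 for r in results],
            "coefficient2": [r.coefficient2 for r in results],
            "vol_a": [r.vol_a for r in results],
            "vol_b": [r.vol_b for r in results],
            "vol_ab": [r.vol_ab for r in results],
            "empty_a": [r.empty_a for r in results],
            "empty_b": [r.empty_b for r in results],
        }
    )


def write_coloc_csv(results: Sequence[ColocResult], path) -> Path:
    path = Path(path)
    coloc_results_frame(results).to_csv(path, index=False, float_format="%.4f")
    return path


def write_ministack_outputs(table: MinistackTable, csv_path, json_path) -> None:
    """Per-stack CSV plus pie-chart-ready category-fraction JSON."""
    table.table.to_csv(csv_path, index=False, float_format="%.4f")
    payload = {
        "fractions": table.fractions,
        "n_stacks": int(len(table.table)),
        "presence_min": table.presence_min,
        "cell_id": table.cell_id,
        "flags": table.flags,
    }
    Path(json_path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))


def write_cohort_json(summaries: Sequence[CohortSummary], path) -> Path:
    path = Path(path)
    payload = [
        {
            "label": s.label,
            "n": s.n,
            "mean": s.mean,
            "sem": s.sem,
            "n_excluded": s.n_excluded,
            "values": s.values.tolist(),
        }
        for s in summaries
    ]
    path.write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(output_dir, config_dict: dict, extra: Optional[dict] = None) -> Path:
    """Write a reproducibility manifest: config echo, package version, and a
    checksum for every file in the output directory."""
    from . import __version__

    output_dir = Path(output_dir)
    files = sorted(
        p for p in output_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "config": config_dict,
        "files": {str(p.relative_to(output_dir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = output_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path
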