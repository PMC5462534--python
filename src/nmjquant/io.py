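"""Reading and writing stacks, sections, record tables and configuration.

Stacks travel as OME-TIFF (axes normalized to ``(channel, z, y, x)`` on
read regardless of on-disk layout; physical voxel size taken from OME
metadata when present). Because every classification threshold is a
physical length, a stack without a voxel size — in metadata or supplied
explicitly — is an error, never a guess.

Per-NMJ and per-fiber records are flat CSV with a stable column order
that round-trips losslessly; ground truth and summaries are JSON;
configuration is YAML with a ``thresholds`` block whose defaults mirror
the scoring rules (branch_gap_um=5, denervated_devoid_fraction=0.90,
nucleus_overlap_fraction=0.25).
"""

from __future__ import annotations

import dataclasses
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence, Type

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import ClassificationThresholds, NMJRecord
from .fibers import FiberRecord
from .stack import ConfocalStack, SectionImage

__all__ = [
    "read_stack",
    "write_stack",
    "read_section",
    "write_section",
    "write_records",
    "read_records",
    "write_json",
    "load_config",
    "thresholds_from_config",
    "write_masks",
]


def _ome_physical_sizes(tif: tifffile.TiffFile):
    """(z, y, x) physical sizes and channel names from OME-XML, if present."""
    if not tif.ome_metadata:
        return None, None
    root = ET.fromstring(tif.ome_metadata)
    pixels = next((el for el in root.iter() if el.tag.endswith("Pixels")), None)
    if pixels is None:
        return None, None
    sizes = None
    try:
        sizes = (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        sizes = None
    names = [el.attrib["Name"] for el in pixels if el.tag.endswith("Channel")
             and "Name" in el.attrib] or None
    return sizes, names


def _normalize_axes(data: np.ndarray, axes: str, target: str) -> np.ndarray:
    """Reorder/insert axes so the array matches ``target`` (e.g. 'CZYX')."""
    axes = axes.upper()
    # drop singleton axes not in the target (time, sample...)
    for ax in list(axes):
        if ax not in target:
            i = axes.index(ax)
            if data.shape[i] != 1:
                raise ValueError(f"cannot interpret non-singleton axis {ax!r} in {axes!r}")
            data = np.squeeze(data, axis=i)
            axes = axes.replace(ax, "", 1)
    for ax in target:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in target]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ConfocalStack:
    """Read a TIFF/OME-TIFF z-stack, normalizing axes to (C, Z, Y, X).

    ``voxel_size`` (z, y, x in μm) overrides/provides the physical
    calibration when the file carries none; with neither, this raises.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_vs, meta_names = _ome_physical_sizes(tif)
    data = _normalize_axes(data, axes, "CZYX")
    vs = voxel_size or meta_vs
    if vs is None:
        raise ValueError(
            f"{path} carries no physical voxel size and none was supplied; "
            "all scoring thresholds are in μm, so the calibration is required"
        )
    names = list(channel_names) if channel_names else (
        meta_names if meta_names and len(meta_names) == data.shape[0]
        else [f"ch{i}" for i in range(data.shape[0])]
    )
    return ConfocalStack(data, names, tuple(float(v) for v in vs), provenance=str(path))


def write_stack(stack: ConfocalStack, path: str | Path) -> None:
    """Write an OME-TIFF with physical voxel size and channel names."""
    z, y, x = stack.voxel_size
    tifffile.imwrite(
        Path(path),
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": z, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": y, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": x, "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def read_section(
    path: str | Path,
    pixel_size: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> SectionImage:
    """Read a 2D multichannel TIFF section, axes normalized to (C, Y, X)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_vs, meta_names = _ome_physical_sizes(tif)
    data = _normalize_axes(data, axes, "CYX")
    px = pixel_size if pixel_size is not None else (meta_vs[2] if meta_vs else None)
    if px is None:
        raise ValueError(f"{path} carries no pixel size and none was supplied")
    names = list(channel_names) if channel_names else (
        meta_names if meta_names and len(meta_names) == data.shape[0]
        else [f"ch{i}" for i in range(data.shape[0])]
    )
    return SectionImage(data, names, float(px), provenance=str(path))


def write_section(section: SectionImage, path: str | Path) -> None:
    px = section.pixel_size
    tifffile.imwrite(
        Path(path), section.pixels, ome=True,
        metadata={
            "axes": "CYX",
            "PhysicalSizeY": px, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": px, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeZ": 1.0, "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(section.channel_names)},
        },
    )


def write_masks(seg, path: str | Path) -> None:
    """Export post/pre/nucleus masks as a uint8 multi-channel TIFF."""
    data = np.stack([
        seg.post_mask.astype(np.uint8),
        seg.pre_mask.astype(np.uint8),
        (seg.nucleus_labels > 0).astype(np.uint8),
    ])
    tifffile.imwrite(Path(path), data, metadata={"axes": "CZYX"})


# ---------------------------------------------------------------------------
# record tables


def _record_columns(record_type: Type) -> list[str]:
    return [f.name for f in dataclasses.fields(record_type)]


def write_records(
    records: Sequence, path: str | Path, record_type: Type = NMJRecord
) -> None:
    """Write records as CSV, one row per NMJ/fiber, stable column order.

    An empty list writes a header-only file for the given record type.
    """
    if records:
        record_type = type(records[0])
    cols = _record_columns(record_type)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(Path(path), index=False)


def read_records(path: str | Path, record_type: Type = NMJRecord) -> list:
    """Read a record CSV back into dataclass instances (lossless round-trip)."""
    df = pd.read_csv(Path(path))
    out = []
    types = {f.name: f.type for f in dataclasses.fields(record_type)}
    for _, row in df.iterrows():
        kwargs = {}
        for f in dataclasses.fields(record_type):
            v = row[f.name]
            t = types[f.name]
            if t in ("int", int):
                v = int(v)
            elif t in ("float", float):
                v = float(v)
            elif t in ("bool", bool):
                v = bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"
            elif t in ("str", str):
                v = "" if (isinstance(v, float) and np.isnan(v)) else str(v)
            elif "tuple" in str(t):
                v = tuple(float(s) for s in str(v).strip("()").split(",") if s.strip())
            kwargs[f.name] = v
        out.append(record_type(**kwargs))
    return out


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG = {
    "thresholds": {
        "branch_gap_um": 5.0,
        "denervated_devoid_fraction": 0.90,
        "postsyn_branch_min_um": 5.0,
        "nucleus_overlap_fraction": 0.25,
        "min_elaborate_branches": 2,
    },
    "morphometry": {
        "smooth_sigma_um": 0.2,
        "reach_radius_um": 1.0,
        "apposition_radius_um": 1.0,
    },
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, merged over the built-in defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if key in cfg and isinstance(val, dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def thresholds_from_config(cfg: dict) -> ClassificationThresholds:
    return ClassificationThresholds.from_config(cfg.get("thresholds"))
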