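"""File plumbing: NIfTI series, sidecar metadata, configuration files, tables.

An encoded series is stored as three 4-D NIfTI volumes (``*_mag.nii``,
``*_phx.nii``, ``*_phy.nii``; frames along the 4th axis, float64 so the
round trip is bit-exact) plus a JSON sidecar carrying the encoding metadata
(``k_e`` per axis, pixel spacing in mm, frame interval in ms, and the full
encoding configuration).  Phantom ground truth can be exported as NIfTI
displacement maps plus a delimited truth-curve table.  Configuration files
are YAML with ``phantom:`` / ``encoding:`` / ``experiment:`` sections mapping
one-to-one onto the dataclass fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .encode import DenseSeries, EncodingConfig
from .phantom import PhantomConfig, PhantomTruth

__all__ = [
    "save_series",
    "load_series",
    "save_truth",
    "load_config",
    "phantom_config_from_dict",
    "encoding_config_from_dict",
]


def _affine(pixel_mm: float) -> np.ndarray:
    aff = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    return aff


def _to_nifti(frames: np.ndarray, pixel_mm: float) -> nib.Nifti1Image:
    # (T, H, W) -> (W, H, T) so x/y are the first two NIfTI axes
    vol = np.transpose(frames, (2, 1, 0)).astype(np.float64)
    return nib.Nifti1Image(vol[:, :, None, :], _affine(pixel_mm))


def _from_nifti(img: nib.Nifti1Image) -> np.ndarray:
    vol = np.asarray(img.dataobj, dtype=np.float64)[:, :, 0, :]
    return np.transpose(vol, (2, 1, 0))


def save_series(series: DenseSeries, prefix: str | Path) -> dict[str, Path]:
    """Write magnitude/phase volumes and the JSON sidecar; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, data in (
        ("mag", series.magnitude),
        ("phx", series.phase_x),
        ("phy", series.phase_y),
    ):
        p = prefix.parent / f"{prefix.name}_{tag}.nii"
        nib.save(_to_nifti(data, series.pixel_mm), p)
        paths[tag] = p
    enc = dataclasses.asdict(series.encoding)
    sidecar = {
        "ke_cycles_per_mm": series.encoding.ke_cycles_per_mm,
        "pixel_mm": series.pixel_mm,
        "frame_ms": series.frame_ms,
        "encoding": enc,
    }
    p = prefix.parent / f"{prefix.name}_meta.json"
    p.write_text(json.dumps(sidecar, indent=2))
    paths["meta"] = p
    return paths


def load_series(prefix: str | Path) -> DenseSeries:
    """Read a series written by :func:`save_series` (bit-exact)."""
    prefix = Path(prefix)
    meta = json.loads((prefix.parent / f"{prefix.name}_meta.json").read_text())
    enc = encoding_config_from_dict(meta["encoding"])
    arrays = {
        tag: _from_nifti(nib.load(prefix.parent / f"{prefix.name}_{tag}.nii"))
        for tag in ("mag", "phx", "phy")
    }
    return DenseSeries(
        magnitude=arrays["mag"],
        phase_x=arrays["phx"],
        phase_y=arrays["phy"],
        pixel_mm=float(meta["pixel_mm"]),
        frame_ms=float(meta["frame_ms"]),
        encoding=enc,
    )


def save_truth(truth: PhantomTruth, prefix: str | Path) -> dict[str, Path]:
    """Export ground truth: displacement maps (NIfTI) + truth-curve table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ax, tag in enumerate(("ux", "uy")):
        p = prefix.parent / f"{prefix.name}_{tag}.nii"
        nib.save(_to_nifti(truth.eulerian_disp[:, ax], truth.config.pixel_mm), p)
        paths[tag] = p
    p = prefix.parent / f"{prefix.name}_truth_curves.csv"
    truth.truth_curves.to_csv(p, index=False)
    paths["curves"] = p
    return paths


def _filter_fields(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    return PhantomConfig(**_filter_fields(PhantomConfig, dict(d)))


def encoding_config_from_dict(d: dict) -> EncodingConfig:
    return EncodingConfig(**_filter_fields(EncodingConfig, dict(d)))


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file; returns the raw section mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a mapping")
    return cfg
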