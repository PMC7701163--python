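"""On-disk conventions: multi-page TIFF stacks with JSON sidecar
manifests, 32-bit float maps with provenance sidecars, 8-bit masks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .phantoms import AcquisitionStack, StructuredFrame
from .sfdi import StO2Map

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "write_mask",
    "read_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: AcquisitionStack, path) -> Path:
    """Multi-page TIFF (one page per frame) plus a manifest recording
    per-frame (wavelength, fx, phase), provenance, and seed."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack([f.intensity.astype(np.float32) for f in stack.frames]),
    )
    manifest = {
        "frames": [
            {"wavelength_nm": f.wavelength, "fx_mm": f.fx, "phase_rad": f.phase}
            for f in stack.frames
        ],
        "provenance": stack.provenance,
    }
    _sidecar(path).write_text(json.dumps(manifest, indent=2))
    return path


def read_stack(path) -> AcquisitionStack:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    manifest = json.loads(_sidecar(path).read_text())
    frames = [
        StructuredFrame(
            intensity=np.asarray(page, dtype=float),
            wavelength=meta["wavelength_nm"],
            fx=meta["fx_mm"],
            phase=meta["phase_rad"],
        )
        for page, meta in zip(pages, manifest["frames"])
    ]
    return AcquisitionStack(frames=frames, provenance=manifest.get("provenance", {}))


def write_map(sto2_map: StO2Map, path, meta: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, sto2_map.sto2.astype(np.float32))
    sidecar = {"kind": "sto2", "valid_fraction": float(np.mean(sto2_map.valid))}
    if meta:
        sidecar.update(meta)
    _sidecar(path).write_text(json.dumps(sidecar, indent=2))
    write_mask(sto2_map.valid, path.with_name(path.stem + "_valid.tif"))
    return path


def read_map(path) -> StO2Map:
    path = Path(path)
    sto2 = np.asarray(tifffile.imread(path), dtype=float)
    mask_path = path.with_name(path.stem + "_valid.tif")
    valid = read_mask(mask_path) if mask_path.exists() else np.ones(sto2.shape, bool)
    return StO2Map(sto2=sto2, valid=valid)


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))
    return path


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0
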