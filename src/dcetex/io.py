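"""NIfTI and configuration I/O.

Volumes travel as NIfTI (.nii or .nii.gz) with the affine preserved;
binary masks are written as uint8.  Acquisition timing (timepoints and
bolus duration tau) lives in a JSON sidecar next to the 4D series.
Voxel indices are 0-based with axis order (x, y, z, t) throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .pk import DceSeries

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "load_series",
    "save_series",
    "load_config",
    "save_config",
    "config_hash",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume -> (data, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - message content only
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, img.affine


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    data, affine = read_volume(path)
    return data.astype(bool), affine


def write_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    write_volume(path, np.asarray(mask, dtype=np.uint8), affine)


def _sidecar_path(series_path: Path) -> Path:
    name = series_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return series_path.with_name(name[: -len(suffix)] + ".json")
    return series_path.with_suffix(".json")


def save_series(path, series: DceSeries, affine: np.ndarray | None = None) -> None:
    """Write the 4D series plus a JSON sidecar with timing metadata."""
    path = Path(path)
    write_volume(path, series.intensities, affine)
    sidecar = {
        "timepoints_seconds": [float(t) for t in series.timepoints],
        "tau_seconds": float(series.tau),
        "voxel_spacing_mm": [float(v) for v in series.voxel_spacing],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_series(path, timepoints=None, tau: float | None = None) -> tuple[DceSeries, np.ndarray]:
    """Read a 4D series; timing from the sidecar unless given explicitly."""
    path = Path(path)
    data, affine = read_volume(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if timepoints is None:
        timepoints = meta.get("timepoints_seconds")
    if timepoints is None:
        raise ValueError(f"no timepoints given and no sidecar at {sidecar}")
    if tau is None:
        tau = meta.get("tau_seconds", 7.0)
    spacing = tuple(meta.get("voxel_spacing_mm", (1.25, 1.25, 2.5)))
    return DceSeries(data, np.asarray(timepoints, float), float(tau), spacing), affine


def load_config(path) -> dict:
    """Read a YAML or JSON run configuration into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    else:
        path.write_text(json.dumps(config, indent=2, sort_keys=True))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (provenance stamping)."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
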