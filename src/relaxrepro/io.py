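"""NIfTI + JSON-sidecar serialization for series, masks, maps and truth.

Multi-echo series are 4-D NIfTI (x, y, slice, echo) with a JSON sidecar
carrying the echo-time vector (ms) and acquisition metadata; label masks
are uint8 volumes (0 = background, 1 = tumor, 2 = muscle); parametric maps
and phantom truth are stacked 4-D volumes whose component order and units
are recorded in their sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import EchoSeries
from .phantom import PhantomVolume, ROISet
from .protocols import Protocol
from .relaxometry import ParametricMap

__all__ = [
    "save_series", "load_series", "save_roi", "load_roi",
    "save_map", "load_map", "save_phantom_truth",
]


def _affine(slice_thickness: float) -> np.ndarray:
    return np.diag([1.0, 1.0, float(slice_thickness), 1.0])


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_series(series: EchoSeries, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a 4-D series as NIfTI plus its JSON sidecar; returns the sidecar path."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    img = nib.Nifti1Image(series.voxels.astype(np.float32), _affine(series.protocol.slice_thickness))
    nib.save(img, str(path))
    meta = {
        "echo_times_ms": list(series.protocol.echo_times),
        "field_strength": series.protocol.field_strength,
        "weighting": series.protocol.weighting,
        "slice_thickness_mm": series.protocol.slice_thickness,
        "protocol_name": series.protocol.name,
        "subject_id": series.subject_id,
        "acquisition_index": series.acquisition_index,
        "contrast_state": series.contrast_state,
        "seed": series.seed,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def load_series(path: str | Path, sidecar: str | Path | None = None) -> EchoSeries:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    data = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    protocol = Protocol(
        name=meta.get("protocol_name", "loaded"),
        field_strength=float(meta["field_strength"]),
        weighting=meta["weighting"],
        echo_times=tuple(meta["echo_times_ms"]),
        matrix=(data.shape[0], data.shape[1]),
        n_slices=data.shape[2],
        slice_thickness=float(meta.get("slice_thickness_mm", 1.0)),
    )
    return EchoSeries(
        voxels=data,
        protocol=protocol,
        subject_id=meta.get("subject_id", "subject0"),
        acquisition_index=int(meta.get("acquisition_index", 1)),
        contrast_state=meta.get("contrast_state", "pre"),
        seed=meta.get("seed"),
    )


def save_roi(roi: ROISet, path: str | Path, slice_thickness: float = 1.0) -> None:
    """Write tumor/muscle masks as a uint8 label volume (1 = tumor, 2 = muscle)."""
    labels = np.zeros(roi.tumor_mask.shape, dtype=np.uint8)
    labels[roi.muscle_mask] = 2
    labels[roi.tumor_mask] = 1
    nib.save(nib.Nifti1Image(labels, _affine(slice_thickness)), str(path))


def load_roi(path: str | Path, reader_id: str = "reader0") -> ROISet:
    labels = np.asarray(nib.load(str(path)).get_fdata())
    return ROISet(tumor_mask=labels == 1, muscle_mask=labels == 2, reader_id=reader_id)


_MAP_COMPONENTS = ["T_ms", "A", "S0", "valid", "rss"]


def save_map(pmap: ParametricMap, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a parametric map as stacked 4-D NIfTI (T, A, S0, valid, rss)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    stack = np.stack(
        [pmap.T_map, pmap.A_map, pmap.S0_map, pmap.valid_mask.astype(float), pmap.rss_map],
        axis=3,
    ).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, _affine(pmap.protocol.slice_thickness)), str(path))
    meta = {
        "components": _MAP_COMPONENTS,
        "units": {"T_ms": "ms", "A": "signal", "S0": "signal", "valid": "bool", "rss": "signal^2"},
        "echo_times_ms": list(pmap.protocol.echo_times),
        "field_strength": pmap.protocol.field_strength,
        "weighting": pmap.protocol.weighting,
        "protocol_name": pmap.protocol.name,
        "slice_thickness_mm": pmap.protocol.slice_thickness,
    }
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return sidecar


def load_map(path: str | Path, sidecar: str | Path | None = None) -> ParametricMap:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else _sidecar_path(path)
    meta = json.loads(sidecar.read_text())
    stack = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    protocol = Protocol(
        name=meta.get("protocol_name", "loaded"),
        field_strength=float(meta["field_strength"]),
        weighting=meta["weighting"],
        echo_times=tuple(meta["echo_times_ms"]),
        matrix=(stack.shape[0], stack.shape[1]),
        n_slices=stack.shape[2],
        slice_thickness=float(meta.get("slice_thickness_mm", 1.0)),
    )
    return ParametricMap(
        T_map=stack[..., 0], A_map=stack[..., 1], S0_map=stack[..., 2],
        valid_mask=stack[..., 3] > 0.5, rss_map=stack[..., 4], protocol=protocol,
    )


def save_phantom_truth(phantom: PhantomVolume, path: str | Path, slice_thickness: float = 1.0) -> None:
    """Write latent truth as stacked 4-D NIfTI (true_T, true_S0, true_A, labels)."""
    stack = np.stack(
        [phantom.true_T, phantom.true_S0, phantom.true_A, phantom.labels.astype(float)], axis=3
    ).astype(np.float32)
    nib.save(nib.Nifti1Image(stack, _affine(slice_thickness)), str(path))
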