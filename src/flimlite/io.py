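"""File formats: HDF5 cubes, TIFF label masks, text decays, CSV tables,
JSON sidecars.

The native HDF5 dialect stores one dataset ``/counts`` ordered
``(time, row, col)`` with attributes ``period_ns`` and ``bin_centers_ns``;
an :class:`HDF5Layout` can remap the dataset path, the time-axis position
and the period source so third-party cube files can be ingested without
code changes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import DecayCurve, FLIDataset, LabelMask, TimeAxis
from .errors import ConfigurationError, FormatError, ValidationError
from .phasor import Phasor, PhasorCalibration, ReferencePair
from .roi import ROI, ROISet

__all__ = [
    "HDF5Layout",
    "read_dataset",
    "write_dataset",
    "read_label_mask",
    "write_label_mask",
    "read_decay_text",
    "write_decay_text",
    "export_table",
    "save_json_sidecar",
    "load_json_sidecar",
]

SCHEMA_VERSION = 1


@dataclass
class HDF5Layout:
    """Where to find the cube inside an HDF5 container."""

    dataset_path: str = "/counts"
    time_axis: int = 0
    period_attr: str = "period_ns"
    bin_centers_attr: str = "bin_centers_ns"
    period_ns: float | None = None  # override when the file has no attribute


def read_dataset(path: "str | Path", layout: HDF5Layout | None = None) -> FLIDataset:
    """Read a time-resolved cube from HDF5, reordering to (time, row, col)."""
    layout = layout or HDF5Layout()
    with h5py.File(path, "r") as f:
        if layout.dataset_path not in f:
            raise FormatError(f"no dataset {layout.dataset_path!r} in {path}")
        dset = f[layout.dataset_path]
        counts = np.asarray(dset)
        if counts.ndim != 3:
            raise FormatError(f"dataset {layout.dataset_path!r} is not 3-D")
        counts = np.moveaxis(counts, layout.time_axis, 0)
        if np.any(counts < 0):
            raise ValidationError(f"{path} contains negative counts")
        attrs = dict(dset.attrs)
        period = attrs.get(layout.period_attr, layout.period_ns)
        if period is None:
            raise ConfigurationError(
                f"no {layout.period_attr!r} attribute in {path} and no layout override"
            )
        period = float(period)
        centers = attrs.get(layout.bin_centers_attr)
        if centers is not None:
            axis = TimeAxis(counts.shape[0], period, np.asarray(centers, float))
        else:
            axis = TimeAxis.regular(counts.shape[0], period)
        meta: dict[str, Any] = {}
        for k, v in attrs.items():
            if k in (layout.period_attr, layout.bin_centers_attr):
                continue
            meta[k] = v.item() if isinstance(v, np.generic) else v
        if "meta" in f:
            for k, v in f["meta"].attrs.items():
                meta[k] = v.item() if isinstance(v, np.generic) else v
    return FLIDataset(counts=counts, time_axis=axis, meta=meta)


def write_dataset(ds: FLIDataset, path: "str | Path") -> Path:
    """Write a dataset in the native dialect; inverse of :func:`read_dataset`."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("counts", data=ds.counts)
        dset.attrs["period_ns"] = ds.time_axis.period_ns
        dset.attrs["bin_centers_ns"] = ds.time_axis.bin_centers_ns
        grp = f.create_group("meta")
        for k, v in ds.meta.items():
            if isinstance(v, (str, int, float, np.generic, bool)):
                grp.attrs[str(k)] = v
    return path


def read_label_mask(path: "str | Path") -> LabelMask:
    """Read an integer-label TIFF (StarDist/Fiji export style)."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"label mask {path} must be a single 2-D plane, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"label mask {path} has non-integral values")
        arr = arr.astype(np.int64)
    try:
        return LabelMask(labels=arr)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_label_mask(mask: LabelMask, path: "str | Path") -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.int32))
    return path


def read_decay_text(path: "str | Path", axis: TimeAxis | None = None) -> DecayCurve:
    """Read a 1- or 2-column delimited text decay.

    Two columns are (time_ns, counts); a counts-only file takes its time
    grid from ``axis``. A single non-numeric header line is skipped; any
    later non-numeric row is a parse error.
    """
    rows: list[list[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").replace(";", " ").replace("\t", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header
                raise FormatError(f"non-numeric row at {path}:{lineno}: {line!r}") from None
    if not rows:
        raise FormatError(f"{path} contains no numeric data")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() not in (1, 2):
        raise FormatError(f"{path} must have 1 or 2 numeric columns throughout")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] == 2:
        return DecayCurve(time_ns=data[:, 0], counts=data[:, 1])
    if axis is None:
        raise ConfigurationError(
            f"{path} has counts only; a TimeAxis is required for the time column"
        )
    if data.shape[0] != axis.n_bins:
        raise FormatError(
            f"{path} has {data.shape[0]} rows but the time axis has {axis.n_bins} bins"
        )
    return DecayCurve(time_ns=axis.bin_centers_ns.copy(), counts=data[:, 0])


def write_decay_text(d: DecayCurve, path: "str | Path") -> Path:
    path = Path(path)
    np.savetxt(path, np.column_stack([d.time_ns, d.counts]), fmt="%.12g", delimiter="\t")
    return path


def export_table(rows: "dict[str, Any] | pd.DataFrame", path: "str | Path") -> Path:
    """Write named numeric columns to CSV (header row, >= 9 sig. digits)."""
    if isinstance(rows, dict):
        lengths = {k: len(np.atleast_1d(v)) for k, v in rows.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(f"ragged columns: {lengths}")
        rows = pd.DataFrame(rows)
    path = Path(path)
    rows.to_csv(path, index=False, float_format="%.12g")
    return path


# --- JSON sidecars -----------------------------------------------------------

def _phasor_to_json(p: Phasor) -> dict:
    return {"g": p.g, "s": p.s, "harmonic": p.harmonic, "frequency_MHz": p.frequency_MHz}


def _phasor_from_json(d: dict) -> Phasor:
    return Phasor(
        g=d["g"], s=d["s"], harmonic=d.get("harmonic", 1),
        frequency_MHz=d.get("frequency_MHz"),
    )


def save_json_sidecar(obj: "PhasorCalibration | ReferencePair | ROISet", path: "str | Path") -> Path:
    """Persist a calibration, reference pair or ROI set as versioned JSON."""
    if isinstance(obj, ReferencePair):
        payload = {
            "schema": "flimlite.reference_pair",
            "version": SCHEMA_VERSION,
            "p1": _phasor_to_json(obj.p1),
            "p2": _phasor_to_json(obj.p2),
            "tau1_ns": obj.tau1_ns,
            "tau2_ns": obj.tau2_ns,
            "message": obj.message,
        }
    elif isinstance(obj, PhasorCalibration):
        if obj.mode != "single":
            raise ValidationError("only single-phasor calibrations have a JSON sidecar")
        payload = {
            "schema": "flimlite.calibration",
            "version": SCHEMA_VERSION,
            "mode": obj.mode,
            "phasor": _phasor_to_json(obj.phasor),
            "reference_lifetime_ns": obj.reference_lifetime_ns,
        }
    elif isinstance(obj, ROISet):
        payload = {
            "schema": "flimlite.roi_set",
            "version": SCHEMA_VERSION,
            "shape": list(obj.shape),
            "rois": [
                {"id": r.id, "name": r.name, "pixels": sorted(map(list, r.pixels))}
                for r in obj.rois
            ],
        }
    else:
        raise ValidationError(f"no JSON sidecar defined for {type(obj).__name__}")
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_json_sidecar(path: "str | Path"):
    """Load a sidecar written by :func:`save_json_sidecar`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "schema" not in payload:
        raise FormatError(f"{path} is not a flimlite sidecar (no schema field)")
    if payload.get("version") != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema version {payload.get('version')!r} != {SCHEMA_VERSION}"
        )
    schema = payload["schema"]
    try:
        if schema == "flimlite.reference_pair":
            return ReferencePair(
                p1=_phasor_from_json(payload["p1"]),
                p2=_phasor_from_json(payload["p2"]),
                tau1_ns=payload["tau1_ns"],
                tau2_ns=payload["tau2_ns"],
                message=payload.get("message", ""),
            )
        if schema == "flimlite.calibration":
            return PhasorCalibration(
                mode=payload["mode"],
                phasor=_phasor_from_json(payload["phasor"]),
                reference_lifetime_ns=payload["reference_lifetime_ns"],
            )
        if schema == "flimlite.roi_set":
            return ROISet(
                rois=[
                    ROI(
                        id=r["id"],
                        name=r.get("name"),
                        pixels=frozenset((int(a), int(b)) for a, b in r["pixels"]),
                    )
                    for r in payload["rois"]
                ],
                shape=tuple(payload["shape"]),
            )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc
    raise FormatError(f"{path}: unknown schema {schema!r}")
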