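"""Readers and writers for recordings, models and meshes.

Recordings travel as plain CSV (comma-separated, dot decimal, one header
line, UTF-8) with the four channels ``time_s, displacement_mm, force_n,
torque_nm`` — the shape a test-machine export would have — plus a JSON
sidecar ``<name>.meta.json`` carrying sample id, test kind, feed rate and
reamer diameter.  Spline models serialize to JSON (knots, node values,
slopes, per-segment coefficients, kind, channel, error report).  Meshes go
through trimesh (STL/OBJ/PLY).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError
from .records import ReamingRecord
from .spline import SplineMaterialModel

CHANNEL_COLUMNS = ("time_s", "displacement_mm", "force_n", "torque_nm")
META_KEYS = ("sample_id", "test_kind", "feed_rate_mm_per_s", "reamer_diameter_mm")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(rec: ReamingRecord, path: Union[str, Path]) -> Path:
    """Write a recording as CSV plus its JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame({
        "time_s": rec.time,
        "displacement_mm": rec.displacement,
        "force_n": rec.force,
        "torque_nm": rec.torque,
    })
    frame.to_csv(path, index=False)
    meta = {
        "sample_id": rec.sample_id,
        "test_kind": rec.test_kind,
        "feed_rate_mm_per_s": rec.feed_rate,
        "reamer_diameter_mm": rec.reamer_diameter,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_recording(path: Union[str, Path]) -> ReamingRecord:
    """Read a CSV recording (with sidecar) back into a validated record.

    Raises :class:`FormatError` when a channel column or the sidecar is
    missing or malformed; unit and invariant violations surface as
    :class:`ValidationError` from the record constructor.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed sidecar {sidecar}: {exc}") from exc
    missing = [k for k in META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"sidecar lacks keys: {missing}")

    frame = pd.read_csv(path)
    absent = [c for c in CHANNEL_COLUMNS if c not in frame.columns]
    if absent:
        raise FormatError(f"recording lacks channels: {absent}")
    return ReamingRecord(
        sample_id=str(meta["sample_id"]),
        test_kind=str(meta["test_kind"]),
        feed_rate=float(meta["feed_rate_mm_per_s"]),
        reamer_diameter=float(meta["reamer_diameter_mm"]),
        time=frame["time_s"].to_numpy(float),
        displacement=frame["displacement_mm"].to_numpy(float),
        force=frame["force_n"].to_numpy(float),
        torque=frame["torque_nm"].to_numpy(float),
    )


def save_model(model: SplineMaterialModel, path: Union[str, Path]) -> Path:
    """Serialize a spline material model to JSON."""
    path = Path(path)
    payload = {
        "format": "reamsim-spline-model",
        "version": 1,
        "kind": model.kind,
        "channel": model.channel,
        "knots": model.knots.tolist(),
        "node_values": model.node_values.tolist(),
        "node_slopes": None if model.node_slopes is None else model.node_slopes.tolist(),
        "segments": model.coefficients.tolist(),
        "error_report": model.error_report,
    }
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


def load_model(path: Union[str, Path]) -> SplineMaterialModel:
    """Read a spline material model back from JSON (inverse of save_model)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such model file: {path}")
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed model file {path}: {exc}") from exc
    if payload.get("format") != "reamsim-spline-model":
        raise FormatError(f"{path} is not a spline model file")
    try:
        slopes = payload["node_slopes"]
        return SplineMaterialModel(
            kind=payload["kind"],
            knots=np.asarray(payload["knots"], float),
            node_values=np.asarray(payload["node_values"], float),
            coefficients=np.asarray(payload["segments"], float),
            node_slopes=None if slopes is None else np.asarray(slopes, float),
            channel=payload["channel"],
            error_report=payload.get("error_report", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"model schema mismatch in {path}: {exc}") from exc


def load_mesh(path: Union[str, Path]) -> trimesh.Trimesh:
    """Load a triangulated surface mesh (STL/OBJ/PLY) via trimesh."""
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    return mesh
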