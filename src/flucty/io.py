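"""File I/O: multi-page TIFF stacks with YAML sidecars, CSV traces/decays.

TIFF carries only pixel data (one grayscale page per frame, uint16 for
counts, float32 for maps); all physical metadata — scan geometry, detector
mode, camera calibration, ground truth when the stack is synthetic — lives
in a YAML sidecar next to the image, because TIFF tags are not a reliable
transport for dwell/line timing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import DecayHistogram, PointTrace, RasterScanStack, ScanGeometry

__all__ = [
    "write_stack",
    "read_stack",
    "write_trace",
    "read_trace",
    "write_decay",
    "read_decay",
    "sidecar_path",
    "write_report",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".yaml")


def _geometry_to_dict(geom: ScanGeometry) -> dict:
    return {
        "nx": geom.nx,
        "ny": geom.ny,
        "pixel_size_um": geom.pixel_size,
        "pixel_dwell_us": geom.pixel_dwell,
        "line_time_ms": geom.line_time_s * 1e3,
        "frame_time_s": geom.frame_time_s,
        "n_frames": geom.n_frames,
    }


def _geometry_from_dict(d: dict) -> ScanGeometry:
    return ScanGeometry(
        nx=int(d["nx"]),
        ny=int(d["ny"]),
        pixel_size=float(d["pixel_size_um"]),
        pixel_dwell=float(d["pixel_dwell_us"]),
        line_time=float(d["line_time_ms"]),
        frame_time=float(d["frame_time_s"]),
        n_frames=int(d["n_frames"]),
    )


def write_stack(stack: RasterScanStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar.

    Photon-counting frames are stored as uint16 (counts above 65535 are
    clipped with a warning in the sidecar); camera frames as float32.
    """
    path = Path(path)
    frames = stack.frames
    clipped = False
    if stack.detector_mode == "photon_counting":
        clipped = bool(frames.max(initial=0) > 65535)
        data = np.clip(frames, 0, 65535).astype(np.uint16)
    else:
        data = frames.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "geometry": _geometry_to_dict(stack.geometry),
        "detector_mode": stack.detector_mode,
        "camera_offset": stack.camera_offset,
        "camera_scale": stack.camera_scale,
        "clipped_uint16": clipped,
        "ground_truth": _plain(stack.ground_truth),
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    geometry_override: dict | None = None,
) -> RasterScanStack:
    """Read a multi-page TIFF stack and its YAML sidecar.

    Missing sidecar metadata can be supplied through
    ``geometry_override``; a missing timing field with no override is an
    error naming the field.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError("non-numeric pixel data")
    meta: dict = {}
    sc = Path(sidecar) if sidecar else sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    gd = dict(meta.get("geometry", {}))
    if geometry_override:
        gd.update(geometry_override)
    gd.setdefault("nx", data.shape[2])
    gd.setdefault("ny", data.shape[1])
    gd.setdefault("n_frames", data.shape[0])
    for required in ("pixel_size_um", "pixel_dwell_us"):
        if required not in gd:
            raise ValueError(
                f"missing acquisition metadata {required!r}: provide a sidecar "
                "or a geometry_override"
            )
    gd.setdefault("line_time_ms", gd["nx"] * gd["pixel_dwell_us"] * 1e-3)
    gd.setdefault("frame_time_s", gd["ny"] * gd["line_time_ms"] * 1e-3)
    geom = _geometry_from_dict(gd)
    if (geom.n_frames, geom.ny, geom.nx) != data.shape:
        raise ValueError(
            f"TIFF shape {data.shape} does not match metadata "
            f"({geom.n_frames}, {geom.ny}, {geom.nx})"
        )
    mode = meta.get("detector_mode", "photon_counting")
    if mode == "photon_counting" and not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int64)
    return RasterScanStack(
        frames=data,
        geometry=geom,
        detector_mode=mode,
        camera_offset=float(meta.get("camera_offset", 0.0)),
        camera_scale=float(meta.get("camera_scale", 1.0)),
        ground_truth=meta.get("ground_truth") or {},
    )


def write_trace(trace: PointTrace, path: str | Path) -> Path:
    """Point trace as two-column CSV (time_s, counts)."""
    path = Path(path)
    t = np.arange(len(trace.counts)) * trace.bin_time
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> PointTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    bin_time = float(np.median(np.diff(t)))
    return PointTrace(counts=df["counts"].to_numpy(dtype=np.int64), bin_time=bin_time)


def write_decay(decay: DecayHistogram, path: str | Path) -> Path:
    """Decay histogram as CSV (bin_ns, counts) with the rep rate in a header row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rep_rate_hz,{decay.rep_rate}\n")
        pd.DataFrame(
            {"bin_ns": decay.bin_centers, "counts": decay.counts}
        ).to_csv(fh, index=False)
    return path


def read_decay(path: str | Path) -> DecayHistogram:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# rep_rate_hz"):
            raise ValueError("decay CSV must start with a '# rep_rate_hz,<Hz>' line")
        rep_rate = float(first.split(",")[1])
        df = pd.read_csv(fh)
    return DecayHistogram(
        bin_centers=df["bin_ns"].to_numpy(),
        counts=df["counts"].to_numpy(),
        rep_rate=rep_rate,
    )


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize an analysis report to JSON (numpy-safe)."""
    path = Path(path)
    path.write_text(json.dumps(_plain(report), indent=2, default=str))
    return path
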