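"""File I/O: TIFF movies with JSON sidecars, masks, traces and reports."""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .lightsculpt import ExcitationMap, PhaseMask, SLMGeometry
from .synthetic_movies import AcquisitionSpec, Movie
from .trace_extraction import Trace

__all__ = [
    "write_movie",
    "read_movie",
    "write_phase_mask",
    "read_phase_mask",
    "write_excitation_stack",
    "write_trace",
    "read_trace",
    "write_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path) -> Path:
    """Multi-page 16-bit TIFF plus a JSON sidecar with acquisition,
    protocol and seed metadata; the round trip is lossless."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack")
    meta = {
        "acquisition": dataclasses.asdict(movie.acq),
        "frame_times_ms": movie.frame_times.tolist(),
        "meta": movie.meta,
    }
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_movie(path) -> Movie:
    """Read a movie written by :func:`write_movie`.

    8-bit ("speed-mode") files are promoted to 16-bit with a flag in the
    metadata.  A missing sidecar yields default acquisition parameters
    with a warning.  Truncated files raise naming the bad frame.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise OSError(f"could not read movie {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]

    promoted = False
    if data.dtype == np.uint8:
        data = data.astype(np.uint16)
        promoted = True
    elif data.dtype != np.uint16:
        data = data.astype(np.uint16)

    for i, frame in enumerate(data):
        if frame.shape != data[0].shape:
            raise OSError(f"truncated movie: frame {i} has shape {frame.shape}")

    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        acq = AcquisitionSpec(**meta["acquisition"])
        frame_times = np.asarray(meta["frame_times_ms"], dtype=float)
        extra = meta.get("meta", {})
    else:
        warnings.warn(
            f"no sidecar for {path}; assuming default acquisition parameters",
            stacklevel=2,
        )
        acq = AcquisitionSpec(n_rows=data.shape[1], n_cols=data.shape[2])
        frame_times = np.arange(data.shape[0]) * acq.frame_period
        extra = {}
    if promoted:
        extra = dict(extra, promoted_from_8bit=True)
    return Movie(data=data, acq=acq, frame_times=frame_times, meta=extra)


def write_phase_mask(mask: PhaseMask, path) -> Path:
    """Phase mask as 32-bit float TIFF (radians) with geometry sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mask.phase.astype(np.float32))
    _sidecar(path).write_text(json.dumps(dataclasses.asdict(mask.geometry)))
    return path


def read_phase_mask(path) -> PhaseMask:
    path = Path(path)
    phase = tifffile.imread(path).astype(float)
    sidecar = _sidecar(path)
    if sidecar.exists():
        geom = SLMGeometry(**json.loads(sidecar.read_text()))
    else:
        geom = SLMGeometry(n_rows=phase.shape[0], n_cols=phase.shape[1])
    return PhaseMask(phase=phase, geometry=geom)


def write_excitation_stack(emap: ExcitationMap, path) -> Path:
    """Excitation stack as multi-page float TIFF with um metadata."""
    path = Path(path)
    arr = emap.intensity.astype(np.float32)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    tifffile.imwrite(path, arr)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": emap.pixel_size, "z_step_um": emap.z_step})
    )
    return path


def write_trace(trace: Trace, path) -> Path:
    """Trace as CSV: time, raw_f, baseline, dff."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_ms": trace.time,
            "raw_f": trace.raw_f,
            "baseline_f": trace.baseline_f
            if trace.baseline_f is not None
            else np.nan,
            "dff": trace.dff if trace.dff is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "f0": trace.f0,
        "epochs": [list(e) for e in trace.epochs],
        "photons_per_unit": trace.photons_per_unit,
        "frame_rate": trace.frame_rate,
    }
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    kw = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kw = {
            "f0": meta.get("f0"),
            "epochs": [tuple(e) for e in meta.get("epochs", [])],
            "photons_per_unit": meta.get("photons_per_unit", 1.0),
            "frame_rate": meta.get("frame_rate"),
        }
    return Trace(
        time=df["time_ms"].to_numpy(),
        raw_f=df["raw_f"].to_numpy(),
        baseline_f=df["baseline_f"].to_numpy(),
        dff=df["dff"].to_numpy(),
        **kw,
    )


def write_json(obj: dict, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
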