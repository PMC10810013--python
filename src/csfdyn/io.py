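"""Readers and writers for the external formats the pipeline touches.

ICP recordings arrive as semicolon-separated ``time;pressure`` text (the
acquisition software's export dialect), dilution and intensity data as CSV,
image data as multi-frame grayscale TIFF, and results leave as JSON (plus
CSV for tabular payloads).
"""
from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .datatypes import DyeDilutionSeries, ICPTrace, ROIIntensitySeries

__all__ = [
    "read_icp_trace",
    "write_icp_trace",
    "read_dilution_csv",
    "write_dilution_csv",
    "read_image_stack",
    "read_intensity_csv",
    "write_intensity_csv",
    "write_results",
    "read_results",
]


def read_icp_trace(
    path,
    delimiter: str = ";",
    decimal_mark: str = ".",
    time_unit: str = "s",
    label: str = "",
) -> ICPTrace:
    """Parse a ``time<delimiter>pressure`` text export into an :class:`ICPTrace`.

    Header or comment lines (any line whose first non-blank character is not
    a digit, sign or decimal mark) are skipped. The sampling rate is inferred
    from the median inter-sample spacing rather than trusted from metadata.

    Parameters
    ----------
    path : path-like
        Input text file.
    delimiter : str
        Field separator, ``";"`` for the native export dialect.
    decimal_mark : str
        ``"."`` or ``","`` — both locales occur in the wild.
    time_unit : {"s", "ms", "min"}
        Unit of the time column; converted to seconds.
    """
    scale = {"s": 1.0, "ms": 1e-3, "min": 60.0}.get(time_unit)
    if scale is None:
        raise ValueError(f"unsupported time_unit {time_unit!r}")
    times = []
    pressures = []
    leading = set("0123456789+-" + decimal_mark)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] not in leading:
                continue  # header / comment
            parts = stripped.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
            try:
                if decimal_mark != ".":
                    parts = [p.replace(decimal_mark, ".") for p in parts]
                t = float(parts[0])
                p = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: unparsable value ({exc})") from None
            times.append(t)
            pressures.append(p)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 data lines")
    time = np.asarray(times) * scale
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2
        raise ValueError(f"{path}: time not strictly increasing at data line {bad}")
    rate = 1.0 / float(np.median(dt))
    return ICPTrace(time=time, pressure=np.asarray(pressures), sampling_rate=rate,
                    label=label or str(path))


def write_icp_trace(trace: ICPTrace, path, delimiter: str = ";",
                    decimal_mark: str = ".") -> None:
    """Write a trace back out in the semicolon text dialect (6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        for t, p in zip(trace.time, trace.pressure):
            line = f"{t:.6f}{delimiter}{p:.6f}\n"
            if decimal_mark != ".":
                line = line.replace(".", decimal_mark)
            fh.write(line)


def read_dilution_csv(
    path,
    inflow_reference: Optional[float] = None,
    infusion_rate: Optional[float] = None,
) -> DyeDilutionSeries:
    """Read a plate-reader dilution table.

    Expected columns: ``time_min, rep1, rep2, rep3``. The inflow reference
    (Ci) and infusion rate (ri, µl/min) may be supplied either as
    ``# key = value`` comment rows before the header or as keyword
    arguments (arguments win).
    """
    header_meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        s = line.strip()
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header_meta[k.strip()] = float(v)
        elif s:
            data_lines.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(data_lines)), float_precision="round_trip")
    needed = {"time_min", "rep1", "rep2", "rep3"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[["rep1", "rep2", "rep3"]].isna().any().any():
        bad = df[df[["rep1", "rep2", "rep3"]].isna().any(axis=1)]["time_min"].iloc[0]
        raise ValueError(f"{path}: missing replicate at t={bad:g} min")
    ci = inflow_reference if inflow_reference is not None else header_meta.get("inflow_reference")
    ri = infusion_rate if infusion_rate is not None else header_meta.get("infusion_rate")
    if ci is None or ri is None:
        raise ValueError(f"{path}: inflow_reference and infusion_rate required "
                         "(header rows or arguments)")
    return DyeDilutionSeries(
        sample_times=df["time_min"].to_numpy(),
        outflow_triplicates=df[["rep1", "rep2", "rep3"]].to_numpy(),
        inflow_reference=float(ci),
        infusion_rate=float(ri),
    )


def write_dilution_csv(series: DyeDilutionSeries, path) -> None:
    """Write a dilution series with its metadata header rows."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# inflow_reference = {float(series.inflow_reference)!r}\n")
        fh.write(f"# infusion_rate = {float(series.infusion_rate)!r}\n")
        fh.write("time_min,rep1,rep2,rep3\n")
        for t, (a, b, c) in zip(series.sample_times, series.outflow_triplicates):
            fh.write(f"{float(t)!r},{float(a)!r},{float(b)!r},{float(c)!r}\n")


def read_image_stack(
    path,
    roi: Tuple[int, int, int, int],
    frame_interval: float = 30.0,
) -> ROIIntensitySeries:
    """Mean ROI intensity per frame of a multi-frame grayscale TIFF.

    ``roi`` is an axis-aligned rectangle ``(row0, row1, col0, col1)`` in
    0-based, half-open pixel coordinates. Frame times come from
    ``frame_interval`` seconds (default 30 s, the acquisition cadence).
    The returned series is *not* yet first-frame normalized.
    """
    stack = tifffile.imread(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a grayscale stack, got shape {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 frames, got {stack.shape[0]}")
    r0, r1, c0, c1 = (int(v) for v in roi)
    nr, nc = stack.shape[1], stack.shape[2]
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise ValueError(f"roi {roi} outside image bounds {nr}x{nc}")
    intensity = stack[:, r0:r1, c0:c1].mean(axis=(1, 2)).astype(float)
    times = np.arange(stack.shape[0]) * float(frame_interval)
    return ROIIntensitySeries(frame_times=times, intensity=intensity, normalized=False)


def read_intensity_csv(path) -> ROIIntensitySeries:
    """Read an already-extracted intensity series (``time_s,intensity``)."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_s" not in df.columns or "intensity" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s, intensity")
    normalized = "normalized" in df.columns and bool(df["normalized"].iloc[0])
    return ROIIntensitySeries(frame_times=df["time_s"].to_numpy(),
                              intensity=df["intensity"].to_numpy(),
                              normalized=normalized)


def write_intensity_csv(series: ROIIntensitySeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,intensity,normalized\n")
        flag = int(series.normalized)
        for t, v in zip(series.frame_times, series.intensity):
            fh.write(f"{float(t)!r},{float(v)!r},{flag}\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results, path, *, input_path=None, parameters=None,
                  seed=None, timestamp: bool = True) -> None:
    """Serialize an estimate record to JSON with provenance.

    ``results`` may be a dataclass or a plain dict; provenance covers the
    input file, the parameters used, the package version and (for
    stochastic runs) the seed. Apart from the timestamp field, repeated
    runs on identical input produce byte-identical payloads.
    """
    from . import __version__

    doc = {
        "results": _jsonable(results),
        "provenance": {
            "input": str(input_path) if input_path is not None else None,
            "parameters": _jsonable(parameters) if parameters is not None else None,
            "package": "csfdyn",
            "version": __version__,
            "seed": seed,
            "timestamp": (datetime.now(timezone.utc).isoformat()
                          if timestamp else None),
        },
    }
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
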