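"""Readers and writers for the plain-text exchange formats, plus regridding.

Supported formats
-----------------
* two-column CSV spectra ("x,y", optional single header line)
* a JCAMP-DX subset: single block, uncompressed AFFN ``##XYDATA=(X++(Y..Y))``
  tables and ``##XYPOINTS`` pair lists (DIFDUP/SQZ compression is rejected
  with an explicit error)
* FID CSV ("re,im" columns) with a JSON metadata sidecar carrying ``dwell``
  and ``time``
* similarity-trace CSV ("time,similarity" with ``#``-prefixed metadata)

``resample_series`` places a set of acquisitions onto one common grid by
linear interpolation over the intersection of their axis ranges — never
extrapolating, so no synthetic intensity enters the union/intersection areas
downstream.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from pathlib import Path

import numpy as np

from .datatypes import ComplexSeries, Mode, Spectrum, SpectrumSeries, SimilarityTrace, Technique
from .errors import ParseError, ValidationError

logger = logging.getLogger("specmon")

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcampdx",
    "read_fid_csv",
    "write_fid_csv",
    "resample_series",
    "write_trace_csv",
    "read_trace_csv",
]


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: not a number: {token!r}") from None


def read_spectrum_csv(
    path,
    axis_unit: str = "",
    time: float | None = None,
    technique: Technique = Technique.OTHER,
    mode: Mode = Mode.ABSORPTION,
) -> Spectrum:
    """Read a two-column "x,y" CSV into a :class:`Spectrum`.

    An optional single header line is skipped.  The axis may be stored in
    either direction; the result is ascending.  Duplicate axis values are
    rejected.
    """
    xs: list[float] = []
    ys: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            x_tok, y_tok = row[0].strip(), row[1].strip()
            if lineno == 1:
                try:
                    float(x_tok)
                except ValueError:
                    continue  # header line
            xs.append(_parse_float(x_tok, path, lineno))
            ys.append(_parse_float(y_tok, path, lineno))
    if len(xs) < 2:
        raise ValidationError(f"{path}: fewer than 2 data rows")
    order = np.argsort(xs, kind="stable")
    axis = np.asarray(xs, dtype=float)[order]
    if np.any(np.diff(axis) == 0):
        raise ValidationError(f"{path}: duplicate axis value")
    return Spectrum(
        axis=axis,
        intensity=np.asarray(ys, dtype=float)[order],
        time=time,
        axis_unit=axis_unit,
        technique=technique,
        mode=mode,
    )


def write_spectrum_csv(s: Spectrum, path) -> None:
    with open(path, "w", newline="") as fh:
        for x, y in zip(s.axis, s.intensity):
            fh.write(f"{x:.17g},{y:.17g}\n")


_LDR_RE = re.compile(r"^##\$?([^=]+)=\s*(.*)$")

# AFFN compression markers (SQZ digits, DIF, DUP) — not supported in v1
_COMPRESSED_RE = re.compile(r"[@A-DF-Za-df-z%]")


def read_jcampdx(path) -> Spectrum:
    """Read a single-block JCAMP-DX file (uncompressed AFFN tables only).

    Supports ``##XYDATA=(X++(Y..Y))``, where the axis is reconstructed from
    FIRSTX/LASTX/NPOINTS and each stored Y is multiplied by YFACTOR, and
    ``##XYPOINTS=(XY..XY)`` pair lists with XFACTOR/YFACTOR applied.
    """
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    data_kind: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("$$", 1)[0].rstrip()  # strip inline comments
            if not line:
                continue
            m = _LDR_RE.match(line)
            if m:
                key = m.group(1).replace(" ", "").replace("-", "").replace("_", "").upper()
                val = m.group(2).strip()
                if key in ("XYDATA", "XYPOINTS"):
                    data_kind = key
                    data_lines = []
                    labels[key] = val
                elif key == "END":
                    break
                else:
                    labels[key] = val
            elif data_kind is not None:
                data_lines.append(line)
    if data_kind is None:
        raise ParseError(f"{path}: no ##XYDATA or ##XYPOINTS record")

    def _label_float(key: str, default: float | None = None) -> float:
        if key not in labels:
            if default is not None:
                return default
            raise ParseError(f"{path}: missing required label ##{key}")
        return float(labels[key])

    xunits = labels.get("XUNITS", "")
    yfactor = _label_float("YFACTOR", 1.0)

    if data_kind == "XYDATA":
        if "(X++(Y..Y))" not in labels["XYDATA"].replace(" ", ""):
            raise ParseError(f"{path}: unsupported XYDATA form {labels['XYDATA']!r}")
        firstx = _label_float("FIRSTX")
        lastx = _label_float("LASTX")
        npoints = int(_label_float("NPOINTS"))
        ys: list[float] = []
        for lineno, line in enumerate(data_lines, start=1):
            tokens = line.replace(",", " ").split()
            if not tokens:
                continue
            body = " ".join(tokens[1:])  # first token is the line's X value
            if _COMPRESSED_RE.search(body.replace("e", "").replace("E", "")):
                raise ParseError(
                    f"{path}: unsupported encoding (SQZ/DIF/DUP compression) "
                    f"in XYDATA line {lineno}"
                )
            for tok in tokens[1:]:
                try:
                    ys.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: unsupported encoding in XYDATA token {tok!r}"
                    ) from None
        if len(ys) != npoints:
            raise ParseError(
                f"{path}: NPOINTS={npoints} but {len(ys)} Y values found"
            )
        axis = np.linspace(firstx, lastx, npoints)
        intensity = np.asarray(ys) * yfactor
    else:  # XYPOINTS
        xfactor = _label_float("XFACTOR", 1.0)
        xs, ys = [], []
        for line in data_lines:
            for pair in re.split(r"[;]", line):
                toks = pair.replace(",", " ").split()
                if not toks:
                    continue
                if len(toks) != 2:
                    raise ParseError(f"{path}: malformed XYPOINTS pair {pair!r}")
                xs.append(float(toks[0]) * xfactor)
                ys.append(float(toks[1]) * yfactor)
        axis = np.asarray(xs)
        intensity = np.asarray(ys)

    if axis.size < 2:
        raise ValidationError(f"{path}: fewer than 2 data points")
    return Spectrum(axis=axis, intensity=intensity, axis_unit=xunits)


def read_fid_csv(path, meta_path) -> ComplexSeries:
    """Read a "re,im" CSV plus JSON sidecar {"dwell": s, "time": s}."""
    with open(meta_path) as fh:
        meta = json.load(fh)
    for key in ("dwell", "time"):
        if key not in meta:
            raise ValidationError(f"{meta_path}: sidecar missing key {key!r}")
    re_parts: list[float] = []
    im_parts: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            if lineno == 1:
                try:
                    float(row[0])
                except ValueError:
                    continue  # header
            re_parts.append(_parse_float(row[0].strip(), path, lineno))
            im_parts.append(_parse_float(row[1].strip(), path, lineno))
    if len(re_parts) < 2:
        raise ValidationError(f"{path}: fewer than 2 samples")
    samples = np.asarray(re_parts) + 1j * np.asarray(im_parts)
    return ComplexSeries(samples=samples, dwell=float(meta["dwell"]), time=float(meta["time"]))


def write_fid_csv(fid: ComplexSeries, path, meta_path) -> None:
    with open(path, "w", newline="") as fh:
        for z in fid.samples:
            fh.write(f"{z.real:.17g},{z.imag:.17g}\n")
    with open(meta_path, "w") as fh:
        json.dump({"dwell": fid.dwell, "time": fid.time}, fh)


def resample_series(
    spectra: list[Spectrum], grid: np.ndarray | None = None
) -> SpectrumSeries:
    """Place spectra onto one common grid by linear interpolation.

    The default grid spans the intersection of all axis ranges at the finest
    median spacing among the inputs; values are never extrapolated.  Spectra
    already sharing an identical grid pass through unchanged.
    """
    if not spectra:
        raise ValidationError("need at least one spectrum")
    units = {s.axis_unit for s in spectra}
    if len(units) > 1:
        raise ValidationError(f"mixed axis units: {sorted(units)}")
    ref = spectra[0].axis
    if grid is None and all(
        s.axis.size == ref.size and np.array_equal(s.axis, ref) for s in spectra
    ):
        return SpectrumSeries(spectra=list(spectra))
    if grid is None:
        lo = max(s.axis[0] for s in spectra)
        hi = min(s.axis[-1] for s in spectra)
        if lo >= hi:
            raise ValidationError("axis ranges are disjoint; no common grid")
        step = min(float(np.median(np.diff(s.axis))) for s in spectra)
        n = int(round((hi - lo) / step)) + 1
        grid = np.linspace(lo, hi, n)
    else:
        grid = np.asarray(grid, dtype=float)
        for s in spectra:
            if grid[0] < s.axis[0] - 1e-12 or grid[-1] > s.axis[-1] + 1e-12:
                raise ValidationError("grid extends beyond a spectrum's range")
    out = [
        s.with_intensity(np.interp(grid, s.axis, s.intensity), axis=grid)
        for s in spectra
    ]
    return SpectrumSeries(spectra=out)


def write_trace_csv(trace: SimilarityTrace, path) -> None:
    """Write a trace as "time,similarity" CSV with commented metadata.

    Numeric payload round-trips bit-identically at 17 significant digits.
    """
    if len(trace) == 0:
        raise ValidationError("trace must be nonempty")
    with open(path, "w", newline="") as fh:
        fh.write(f"# metric={trace.metric}\n")
        fh.write(f"# reference={trace.reference}\n")
        fh.write(f"# epsilon={trace.epsilon:.17g}\n")
        if trace.window is not None:
            fh.write(f"# window={trace.window[0]:.17g}:{trace.window[1]:.17g}\n")
        fh.write("time,similarity\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_trace_csv(path) -> SimilarityTrace:
    meta: dict[str, str] = {}
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            row = line.split(",")
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected two columns")
            try:
                float(row[0])
            except ValueError:
                continue  # header
            times.append(_parse_float(row[0], path, lineno))
            values.append(_parse_float(row[1], path, lineno))
    if not times:
        raise ValidationError(f"{path}: no data rows")
    window = None
    if "window" in meta:
        lo, hi = meta["window"].split(":")
        window = (float(lo), float(hi))
    return SimilarityTrace(
        times=np.asarray(times),
        values=np.asarray(values),
        metric=meta.get("metric", ""),
        reference=meta.get("reference", ""),
        epsilon=float(meta.get("epsilon", 0.0)),
        window=window,
    )
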