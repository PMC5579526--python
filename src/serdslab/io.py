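"""Plain-text spectrum I/O.

Dialect: a comment header ``# excitation_nm=<float> axis_kind=<kind>``
followed by CSV with one ``axis`` column and one or more labelled intensity
columns.  For multi-spectrum files (e.g. a shifted-excitation series) an
optional second header ``# columns_excitation_nm=<c1>,<c2>,...`` records the
per-column excitation wavelengths.  Values are written with 17 significant
digits so a write/read cycle is lossless.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_core import AxisKind, Spectrum

__all__ = ["write_spectrum", "read_spectrum", "write_series", "read_series"]

_FMT = "%.17g"


def _header(kind: AxisKind, excitation_nm: float | None) -> str:
    exc = "nan" if excitation_nm is None else _FMT % excitation_nm
    return f"# excitation_nm={exc} axis_kind={kind.value}"


def _parse_header(line: str) -> tuple[AxisKind, float | None]:
    fields = dict(tok.split("=", 1) for tok in line.lstrip("# ").split())
    exc = float(fields["excitation_nm"])
    return AxisKind(fields["axis_kind"]), (None if np.isnan(exc) else exc)


def write_series(spectra: list[Spectrum], path: str | Path,
                 labels: list[str] | None = None) -> None:
    """Write one or more spectra sharing a common axis as labelled columns."""
    if not spectra:
        raise ValueError("nothing to write")
    s0 = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.axis, s0.axis):
            raise ValueError("series spectra must share one axis")
    if labels is None:
        labels = [s.meta.get("label", f"intensity_{i}") for i, s in enumerate(spectra)]
    lines = [_header(s0.axis_kind, s0.excitation_nm)]
    excs = [s.meta.get("acquisition_excitation_nm") for s in spectra]
    if any(e is not None for e in excs):
        lines.append("# columns_excitation_nm=" +
                     ",".join("nan" if e is None else _FMT % float(e) for e in excs))
    df = pd.DataFrame({"axis": s0.axis} |
                      {lab: s.intensity for lab, s in zip(labels, spectra)})
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=_FMT)
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    write_series([spectrum], path, labels=["intensity"])


def read_series(path: str | Path) -> list[Spectrum]:
    text = Path(path).read_text().splitlines()
    kind, exc = _parse_header(text[0])
    col_excs: list[float | None] | None = None
    body_start = 1
    if len(text) > 1 and text[1].startswith("# columns_excitation_nm="):
        raw = text[1].split("=", 1)[1].split(",")
        col_excs = [None if v == "nan" else float(v) for v in raw]
        body_start = 2
    df = pd.read_csv(_io.StringIO("\n".join(text[body_start:])))
    axis = df["axis"].to_numpy()
    out = []
    for j, col in enumerate(c for c in df.columns if c != "axis"):
        meta = {"label": col}
        if col_excs is not None and col_excs[j] is not None:
            meta["acquisition_excitation_nm"] = col_excs[j]
        out.append(Spectrum(axis=axis, intensity=df[col].to_numpy(),
                            axis_kind=kind, excitation_nm=exc, meta=meta))
    return out


def read_spectrum(path: str | Path) -> Spectrum:
    series = read_series(path)
    if len(series) != 1:
        raise ValueError(f"expected a single spectrum, found {len(series)} columns")
    return series[0]
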