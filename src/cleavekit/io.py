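"""Readers and writers for the workbench CSV dialects.

All four dialects are plain comma-separated UTF-8 with '.' decimals and
'#' comment lines. Writers prepend one comment line recording package
version, seed and config hash so every file is traceable to the run that
produced it. Readers reject malformed rows with the file name, 1-based
line number and column; unknown columns are preserved as metadata.

Dialects (required columns first):

=============  ==========================================================
timecourse     time_min, fraction_cleaved [, intensity_fl, intensity_ccp,
               substrate, protease, temp_C, nacl_mM, ...]
titration      enzyme_uM, fraction_cleaved [, substrate, protease,
               time_min, temp_C, s0_uM, ...]
standards      known_fraction, intensity_fl, intensity_ccp
grid (long)    protease, substrate, enzyme_uM, fraction_cleaved,
               time_min, temp_C
=============  ==========================================================
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .densitometry import StandardPoint
from .errors import ParseError
from .estimate import TimeCourse, TitrationSeries

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_titration",
    "write_titration",
    "read_standards",
    "write_standards",
    "read_grid",
    "write_grid",
]

# shortest lossless float representation: numeric fields round-trip exactly
_FLOAT_FMT = "%.17g"


def _provenance_line(config: RunConfig | None, seed: int | None) -> str:
    cfg = config or RunConfig()
    s = cfg.seed if seed is None else seed
    return f"# cleavekit {__version__} seed={s} config_hash={cfg.hash()}\n"


def _read_csv(path, required: Sequence[str]) -> tuple[pd.DataFrame, list[int]]:
    """Parse a dialect file; returns the frame plus the original 1-based
    line number of each data row (for error reporting)."""
    path = Path(path)
    kept: list[str] = []
    line_nos: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for no, line in enumerate(fh, start=1):
            if line.lstrip().startswith("#") or not line.strip():
                continue
            kept.append(line)
            line_nos.append(no)
    if not kept:
        raise ParseError(f"{path}: no data rows")
    header_line = line_nos[0]
    try:
        df = pd.read_csv(_io.StringIO("".join(kept)), float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}:{header_line}: missing required column(s) {missing}"
        )
    return df, line_nos[1:]


def _numeric(df: pd.DataFrame, col: str, path, line_nos: list[int]) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
    if bad.size:
        i = int(bad[0])
        raise ParseError(
            f"{path}:{line_nos[i]}: column {col!r}: non-numeric value "
            f"{df[col].iloc[i]!r}"
        )
    nan = np.flatnonzero(vals.isna().to_numpy())
    if nan.size:
        i = int(nan[0])
        raise ParseError(f"{path}:{line_nos[i]}: column {col!r}: empty cell")
    return vals.to_numpy(dtype=float)


def _check_fraction(f: np.ndarray, col: str, path, line_nos: list[int]) -> None:
    bad = np.flatnonzero((f < 0) | (f > 1))
    if bad.size:
        i = int(bad[0])
        raise ParseError(
            f"{path}:{line_nos[i]}: column {col!r}: value {f[i]!r} outside [0,1]"
        )


def _extras(df: pd.DataFrame, known: Sequence[str]) -> dict:
    """Unknown columns, preserved as metadata (scalar when constant)."""
    out = {}
    for c in df.columns:
        if c in known:
            continue
        col = df[c]
        if col.nunique(dropna=False) == 1:
            out[c] = col.iloc[0]
        else:
            out[c] = col.to_numpy()
    return out


def _write(path, df: pd.DataFrame, config: RunConfig | None, seed: int | None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_line(config, seed))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


# --- time courses ----------------------------------------------------------


def read_timecourse(path) -> TimeCourse:
    df, line_nos = _read_csv(path, ["time_min", "fraction_cleaved"])
    t = _numeric(df, "time_min", path, line_nos)
    f = _numeric(df, "fraction_cleaved", path, line_nos)
    _check_fraction(f, "fraction_cleaved", path, line_nos)
    meta = _extras(df, ["time_min", "fraction_cleaved"])
    for c in ("intensity_fl", "intensity_ccp"):
        if c in df.columns:
            meta[c] = _numeric(df, c, path, line_nos)
    return TimeCourse(t, f, meta)


def write_timecourse(course: TimeCourse, path, config: RunConfig | None = None,
                     seed: int | None = None) -> None:
    _write(path, course.to_frame(), config, seed)


# --- titrations ------------------------------------------------------------


def read_titration(path) -> TitrationSeries:
    df, line_nos = _read_csv(path, ["enzyme_uM", "fraction_cleaved"])
    e = _numeric(df, "enzyme_uM", path, line_nos)
    f = _numeric(df, "fraction_cleaved", path, line_nos)
    _check_fraction(f, "fraction_cleaved", path, line_nos)
    meta = _extras(df, ["enzyme_uM", "fraction_cleaved"])
    return TitrationSeries(e, f, meta)


def write_titration(series: TitrationSeries, path, config: RunConfig | None = None,
                    seed: int | None = None) -> None:
    _write(path, series.to_frame(), config, seed)


# --- cleavage standards ----------------------------------------------------


def read_standards(path) -> list[StandardPoint]:
    cols = ["known_fraction", "intensity_fl", "intensity_ccp"]
    df, line_nos = _read_csv(path, cols)
    arrs = {c: _numeric(df, c, path, line_nos) for c in cols}
    _check_fraction(arrs["known_fraction"], "known_fraction", path, line_nos)
    return [
        StandardPoint(known_fraction=kf, intensity_fl=fl, intensity_ccp=ccp)
        for kf, fl, ccp in zip(arrs["known_fraction"], arrs["intensity_fl"],
                               arrs["intensity_ccp"])
    ]


def write_standards(points: Sequence[StandardPoint], path,
                    config: RunConfig | None = None, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "known_fraction": [p.known_fraction for p in points],
            "intensity_fl": [p.intensity_fl for p in points],
            "intensity_ccp": [p.intensity_ccp for p in points],
        }
    )
    _write(path, df, config, seed)


# --- cross-reactivity grids (long format) ----------------------------------


def read_grid(path) -> pd.DataFrame:
    """Read a long-format grid table.

    Returns the validated DataFrame; completeness of the protease x
    substrate matrix is deliberately NOT checked here — building the
    :class:`~cleavekit.crossreact.CrossReactivityGrid` is where an
    incomplete grid surfaces, with the absent pairs listed.
    """
    df, line_nos = _read_csv(path, ["protease", "substrate", "fraction_cleaved"])
    f = _numeric(df, "fraction_cleaved", path, line_nos)
    _check_fraction(f, "fraction_cleaved", path, line_nos)
    df = df.copy()
    df["fraction_cleaved"] = f
    return df


def write_grid(df: pd.DataFrame, path, config: RunConfig | None = None,
               seed: int | None = None) -> None:
    _write(path, df, config, seed)
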