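"""CSV readers and writers for the typed datasets.

All files are RFC-4180 comma-separated UTF-8 with '.' decimal points and a
header row of required column names; readers validate columns, numeric
content and abscissa uniqueness, and return datasets sorted by abscissa.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from ..datasets import (
    DatasetError,
    FIDTrace,
    HydrationCourse,
    IsothermData,
    SoluteRatios,
    Spectrum,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A CSV file failed structural validation."""


def _read_table(path: PathLike, required: tuple, optional: tuple = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: file contains a header but no data rows")
    cols = list(required) + [c for c in optional if c in df.columns]
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based with header line
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise ParseError(f"{path}: empty cell in column {col!r} at line {row}")
        df[col] = numeric
    dup = df[required[0]].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(
            f"{path}: duplicate {required[0]} value "
            f"{df[required[0]][dup.idxmax()]!r} at line {row}"
        )
    return df


def _wrap(path, ctor, **kwargs):
    try:
        return ctor(**kwargs)
    except DatasetError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_course(
    path: PathLike,
    humidity: Optional[float] = None,
    direction: str = "hydration",
) -> HydrationCourse:
    """Read a gravimetric time course (columns ``time_h, dm_over_m0``)."""
    df = _read_table(path, ("time_h", "dm_over_m0"))
    return _wrap(
        path, HydrationCourse,
        time_h=df["time_h"].to_numpy(), dm_over_m0=df["dm_over_m0"].to_numpy(),
        humidity=humidity, direction=direction,
    )


def read_isotherm(path: PathLike, humidity_unit: str = "fraction") -> IsothermData:
    """Read isotherm points (columns ``p_over_p0, c_h``).

    ``humidity_unit`` is ``"fraction"`` (default) or ``"percent"``; values
    must be supplied consistently in one unit, never mixed.
    """
    if humidity_unit not in ("fraction", "percent"):
        raise ValueError("humidity_unit must be 'fraction' or 'percent'")
    df = _read_table(path, ("p_over_p0", "c_h"))
    h = df["p_over_p0"].to_numpy(dtype=float)
    if humidity_unit == "percent":
        h = h / 100.0
    return _wrap(path, IsothermData, p_over_p0=h, c_h=df["c_h"].to_numpy())


def read_fid(path: PathLike) -> FIDTrace:
    """Read an FID trace (columns ``time_us, amplitude``)."""
    df = _read_table(path, ("time_us", "amplitude"))
    return _wrap(
        path, FIDTrace,
        time_us=df["time_us"].to_numpy(), amplitude=df["amplitude"].to_numpy(),
    )


def read_spectrum(path: PathLike) -> Spectrum:
    """Read a frequency-domain spectrum (columns ``freq_hz, amplitude``)."""
    df = _read_table(path, ("freq_hz", "amplitude"))
    return _wrap(
        path, Spectrum,
        freq_hz=df["freq_hz"].to_numpy(), amplitude=df["amplitude"].to_numpy(),
    )


def read_solute(path: PathLike) -> SoluteRatios:
    """Read ratio data (column ``dm_over_m0`` plus ``l_over_s``/``l1_over_l``)."""
    df = _read_table(path, ("dm_over_m0",), optional=("l_over_s", "l1_over_l"))
    kwargs = {"dm_over_m0": df["dm_over_m0"].to_numpy()}
    for col in ("l_over_s", "l1_over_l"):
        if col in df.columns:
            kwargs[col] = df[col].to_numpy()
    if len(kwargs) == 1:
        raise ParseError(f"{path}: need an l_over_s or l1_over_l column")
    return _wrap(path, SoluteRatios, **kwargs)


# ---------------------------------------------------------------------------
# writers (exact column-name mirrors of the readers)
# ---------------------------------------------------------------------------


def write_course(course: HydrationCourse, path: PathLike) -> None:
    pd.DataFrame(
        {"time_h": course.time_h, "dm_over_m0": course.dm_over_m0}
    ).to_csv(path, index=False)


def write_isotherm(data: IsothermData, path: PathLike) -> None:
    pd.DataFrame({"p_over_p0": data.p_over_p0, "c_h": data.c_h}).to_csv(
        path, index=False
    )


def write_fid(trace: FIDTrace, path: PathLike) -> None:
    pd.DataFrame(
        {"time_us": trace.time_us, "amplitude": trace.amplitude}
    ).to_csv(path, index=False)


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    pd.DataFrame(
        {"freq_hz": spectrum.freq_hz, "amplitude": spectrum.amplitude}
    ).to_csv(path, index=False)


def write_solute(ratios: SoluteRatios, path: PathLike) -> None:
    cols = {"dm_over_m0": ratios.dm_over_m0}
    if ratios.l_over_s is not None:
        cols["l_over_s"] = ratios.l_over_s
    if ratios.l1_over_l is not None:
        cols["l1_over_l"] = ratios.l1_over_l
    pd.DataFrame(cols).to_csv(path, index=False)
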