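"""Lightweight typed containers for the observables the pipeline fits.

Each container holds numpy arrays sorted by abscissa plus the minimum of
metadata needed downstream.  Construction validates shape, finiteness and
abscissa uniqueness so the estimators can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class DatasetError(ValueError):
    """Raised when a dataset fails structural validation."""


def _clean_xy(x, y, xname: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise DatasetError("empty dataset")
    if x.size != y.size:
        raise DatasetError(f"{xname} and ordinate differ in length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DatasetError("non-finite values in dataset")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.any(np.diff(x) == 0):
        dup = x[np.nonzero(np.diff(x) == 0)[0][0]]
        raise DatasetError(f"duplicate {xname} value {dup!r}")
    return x, y


@dataclass(frozen=True)
class HydrationCourse:
    """Gravimetric time course: relative mass gain dm/m0 versus time (h)."""

    time_h: np.ndarray
    dm_over_m0: np.ndarray
    humidity: Optional[float] = None
    direction: str = "hydration"

    def __post_init__(self) -> None:
        t, y = _clean_xy(self.time_h, self.dm_over_m0, "time_h")
        if t[0] < 0:
            raise DatasetError("negative time")
        if self.direction not in ("hydration", "dehydration"):
            raise DatasetError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "dm_over_m0", y)

    def __len__(self) -> int:
        return self.time_h.size


@dataclass(frozen=True)
class IsothermData:
    """Saturation hydration level C^h versus relative humidity p/p0."""

    p_over_p0: np.ndarray
    c_h: np.ndarray

    def __post_init__(self) -> None:
        h, c = _clean_xy(self.p_over_p0, self.c_h, "p_over_p0")
        if h[0] < 0 or h[-1] > 1:
            raise DatasetError("relative humidity must lie in [0, 1]")
        object.__setattr__(self, "p_over_p0", h)
        object.__setattr__(self, "c_h", c)

    def __len__(self) -> int:
        return self.p_over_p0.size


@dataclass(frozen=True)
class FIDTrace:
    """Time-domain NMR signal: amplitude versus time (us)."""

    time_us: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        t, a = _clean_xy(self.time_us, self.amplitude, "time_us")
        if t[0] < 0:
            raise DatasetError("negative time")
        object.__setattr__(self, "time_us", t)
        object.__setattr__(self, "amplitude", a)

    def __len__(self) -> int:
        return self.time_us.size


@dataclass(frozen=True)
class Spectrum:
    """Frequency-domain NMR signal: amplitude versus carrier offset (Hz)."""

    freq_hz: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        f, a = _clean_xy(self.freq_hz, self.amplitude, "freq_hz")
        object.__setattr__(self, "freq_hz", f)
        object.__setattr__(self, "amplitude", a)

    def __len__(self) -> int:
        return self.freq_hz.size

    def freq_ppm(self, carrier_mhz: float = 300.0) -> np.ndarray:
        """Offset axis in ppm for the given carrier frequency."""
        return self.freq_hz / carrier_mhz


@dataclass(frozen=True)
class SoluteRatios:
    """Per-hydration-level NMR signal ratios.

    Either or both of ``l_over_s`` (mobile/solid) and ``l1_over_l``
    (less-mobile liquid / total liquid) may be present; they share the
    hydration abscissa.
    """

    dm_over_m0: np.ndarray
    l_over_s: Optional[np.ndarray] = None
    l1_over_l: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.l_over_s is None and self.l1_over_l is None:
            raise DatasetError("need at least one ratio column")
        dm = np.asarray(self.dm_over_m0, dtype=float).ravel()
        ref = self.l_over_s if self.l_over_s is not None else self.l1_over_l
        dm_sorted, _ = _clean_xy(dm, ref, "dm_over_m0")
        order = np.argsort(dm, kind="stable")
        object.__setattr__(self, "dm_over_m0", dm_sorted)
        for name in ("l_over_s", "l1_over_l"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(col, dtype=float).ravel()
                if col.size != dm.size:
                    raise DatasetError(f"{name} length mismatch")
                if not np.isfinite(col).all():
                    raise DatasetError("non-finite values in dataset")
                object.__setattr__(self, name, col[order])

    def __len__(self) -> int:
        return self.dm_over_m0.size
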