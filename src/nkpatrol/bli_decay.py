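"""Bioluminescence (BLI) time-series processing.

Whole-animal luminescence from luciferase-tagged tumor cells is a proxy for
viable tumor burden. After normalization to the 1-h reference point, the
decay phase follows a power law ``BLI(t) = t^-b`` (t in hours), so the decay
slows with time; the tumor half-life quoted at a reference time ``t_ref`` is
the curve-halving time ``t_ref * (2^(1/b) - 1)``, returned in minutes. An
instantaneous-rate definition ``ln2 * t_ref / b`` is exposed as an
alternative mode. After the nadir (typically 24 h) surviving cells regrow
exponentially; the doubling time comes from a log-linear fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BLISeries",
    "normalize_bli",
    "fit_decay_powerlaw",
    "half_life_at",
    "doubling_time",
    "nadir_time",
    "read_bli",
    "write_bli",
]

#: sentinel for a non-growing series: infinite doubling time
NO_GROWTH = math.inf


@dataclass
class BLISeries:
    """Bioluminescence intensity vs time for one animal.

    Times are hours post tumor injection; intensities are arbitrary photon
    units, strictly positive. ``reference_time`` (default 1 h) anchors the
    normalization.
    """

    animal_id: str
    times: np.ndarray  # h
    intensities: np.ndarray  # a.u.
    reference_time: float = 1.0
    group: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must have equal length")
        if len(self.times) < 2:
            raise ValueError("a BLI series needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.intensities > 0):
            raise ValueError("intensities must be strictly positive")


def _reference_intensity(series: BLISeries) -> float:
    """Intensity at the reference time, interpolated log-log between
    bracketing samples when no sample falls exactly on it (linear in
    log-time vs log-intensity, hence exact on a power-law segment)."""
    t, v = series.times, series.intensities
    t_ref = series.reference_time
    exact = np.isclose(t, t_ref, rtol=0, atol=1e-9)
    if exact.any():
        return float(v[exact][0])
    if t_ref < t[0] or t_ref > t[-1]:
        raise ValueError(
            f"reference time {t_ref} h is not bracketed by samples "
            f"[{t[0]}, {t[-1]}] h"
        )
    if t[0] <= 0:
        return float(np.exp(np.interp(t_ref, t, np.log(v))))
    return float(np.exp(np.interp(np.log(t_ref), np.log(t), np.log(v))))


def normalize_bli(series: BLISeries) -> BLISeries:
    """Divide all intensities by the intensity at the reference time.

    Idempotent: the normalized series has value 1 at the reference time.
    """
    ref = _reference_intensity(series)
    return replace(series, intensities=series.intensities / ref)


def fit_decay_powerlaw(
    series: BLISeries, window: tuple[float, float] = (1.0, 12.0)
) -> float:
    """Fit the decay phase of a *normalized* series with ``BLI(t) = t^-b``.

    Least squares on the linear scale (log-log linear fit as initializer)
    over samples with times inside *window* (hours, inclusive). Returns the
    exponent b. Needs at least three samples in the window.
    """
    t, v = series.times, series.intensities
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    x, y = t[mask], v[mask]
    if len(x) < 3:
        raise ValueError(
            f"need at least 3 samples in window {window}, got {len(x)}"
        )
    # log-log slope; guard the degenerate all-equal-times case via polyfit
    slope = np.polyfit(np.log(x), np.log(y), 1)[0]
    b0 = -float(slope)
    popt, _ = curve_fit(lambda tt, b: tt ** (-b), x, y, p0=[b0], maxfev=10000)
    return float(popt[0])


def half_life_at(
    exponent: float,
    t_ref: float = 4.0,
    mode: Literal["curve", "instantaneous"] = "curve",
) -> float:
    """Tumor half-life in minutes at reference time *t_ref* (hours) for a
    fitted power-law decay ``BLI(t) = t^-exponent``.

    ``mode="curve"`` (default) is the time for the fitted curve to halve
    starting from t_ref: ``t_ref * (2^(1/b) - 1)``. ``mode="instantaneous"``
    converts the local decay rate ``b / t_ref`` into ``ln2 * t_ref / b``.
    """
    if not (math.isfinite(exponent) and exponent > 0):
        raise ValueError(f"decay exponent must be positive, got {exponent!r}")
    if t_ref <= 0:
        raise ValueError(f"t_ref must be positive, got {t_ref!r}")
    if mode == "curve":
        hours = t_ref * (2.0 ** (1.0 / exponent) - 1.0)
    elif mode == "instantaneous":
        hours = math.log(2.0) * t_ref / exponent
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return hours * 60.0


def doubling_time(series: BLISeries, window: tuple[float, float]) -> float:
    """Doubling time (hours) from a log-linear fit over *window* (hours).

    A non-positive growth slope returns the ``NO_GROWTH`` sentinel
    (infinite doubling time).
    """
    t, v = series.times, series.intensities
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    x, y = t[mask], v[mask]
    if len(x) < 2:
        raise ValueError(f"need at least 2 samples in window {window}")
    k = float(np.polyfit(x, np.log(y), 1)[0])  # 1/h
    if k <= 0:
        return NO_GROWTH
    return math.log(2.0) / k


def nadir_time(series: BLISeries) -> float:
    """Time (hours) of the minimum intensity; no smoothing is applied."""
    return float(series.times[int(np.argmin(series.intensities))])


# ---------------------------------------------------------------------------
# I/O


def write_bli(series: Sequence[BLISeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.times, s.intensities):
            rows.append((s.animal_id, s.group, t, v))
    pd.DataFrame(rows, columns=["animal_id", "group", "t_hours", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_bli(path: str | Path) -> list[BLISeries]:
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "t_hours", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"BLI table {path} is missing columns {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    out = []
    for animal_id, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("t_hours")
        out.append(
            BLISeries(
                animal_id=str(animal_id),
                times=g["t_hours"].to_numpy(dtype=float),
                intensities=g["intensity"].to_numpy(dtype=float),
                group=str(g["group"].iloc[0]) if not g["group"].isna().all() else "",
            )
        )
    return out
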