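"""NK-tumor contact detection and contact-outcome statistics.

A *hit* is an NK cell coming within 10 µm (center-to-center, boundary
inclusive) of a lodged tumor cell; the *hit rate* is hits per minute of
summed tumor observation time. Contacting NK cells are classified as
*crawling* (tracked for more than four frames, i.e. 2 min, before contact)
or *flowing* (already in contact at first appearance in the field of view).

Reporter-based outcomes use ratiometric or intensity time series per cell:
ERK activation is a more than 30% rise of the FRET/CFP ratio over the
pre-contact baseline within 3 min of contact; the same threshold machinery
serves calcium-influx (GCaMP) and caspase (inverted FRET) series with
configurable thresholds and windows.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .track_analysis import Track

__all__ = [
    "ContactEvent",
    "ReporterSeries",
    "OutcomeTable",
    "detect_hits",
    "hit_rate",
    "classify_mover",
    "detect_activation",
    "contact_outcome_table",
    "read_events",
    "write_events",
    "read_reporters",
    "write_reporters",
]

HIT_RADIUS_UM = 10.0

_EPS = 1e-9


@dataclass
class ContactEvent:
    """One NK-tumor proximity episode with outcome flags.

    Lags are minutes from ``start_time``. ``censored`` marks events still
    open at the end of the movie.
    """

    event_id: str
    nk_track_id: str
    tumor_id: str
    start_time: float
    end_time: float
    mover_class: str = "indeterminate"  # crawling | flowing | indeterminate
    erk_activated: bool = False
    erk_lag: float | None = None
    ca_influx: bool = False
    ca_lag: float | None = None
    caspase: bool = False
    caspase_lag: float | None = None
    tumor_died: bool = False
    censored: bool = False

    def __post_init__(self):
        if self.end_time < self.start_time:
            raise ValueError("end_time must be >= start_time")
        for name in ("erk_lag", "ca_lag", "caspase_lag"):
            lag = getattr(self, name)
            if lag is not None and lag < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ReporterSeries:
    """Per-cell reporter time series (FRET ratio, GCaMP intensity, ...)."""

    cell_id: str
    channel: str  # fret_ratio | gcamp | scat3_ratio
    times: np.ndarray  # min
    values: np.ndarray  # a.u.
    baseline_window: float = 2.0  # min before contact used as baseline

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) < 2:
            raise ValueError("a reporter series needs at least two samples")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reporter values must be finite")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("reporter times must be strictly increasing")


# ---------------------------------------------------------------------------
# hit detection


def detect_hits(
    nk_tracks: Sequence[Track],
    tumor_tracks: Sequence[Track],
    radius: float = HIT_RADIUS_UM,
) -> list[ContactEvent]:
    """Scan all NK-tumor pairs for proximity episodes.

    A hit opens at the first common frame with center-to-center distance
    <= *radius* (inclusive) and closes at the first observed frame beyond it;
    re-entry starts a new event. An episode still within radius at the last
    common frame is closed there, and flagged censored when that frame is the
    end of the movie. All tracks must share the frame grid.
    """
    if not nk_tracks or not tumor_tracks:
        return []
    interval = nk_tracks[0].frame_interval
    for tr in list(nk_tracks) + list(tumor_tracks):
        if abs(tr.frame_interval - interval) > 1e-9:
            raise ValueError(
                f"track {tr.track_id}: frame interval {tr.frame_interval} "
                f"does not match {interval}"
            )
    movie_end = max(tr.times[-1] for tr in list(nk_tracks) + list(tumor_tracks))

    events: list[ContactEvent] = []
    for nk in nk_tracks:
        nk_frames = np.rint(nk.times / interval).astype(int)
        nk_map = dict(zip(nk_frames, range(len(nk_frames))))
        for tumor in tumor_tracks:
            tu_frames = np.rint(tumor.times / interval).astype(int)
            common = sorted(set(nk_frames) & set(tu_frames))
            if not common:
                continue
            tu_map = dict(zip(tu_frames, range(len(tu_frames))))
            open_start: float | None = None
            last_in: float | None = None
            for f in common:
                d = np.linalg.norm(
                    nk.positions[nk_map[f]] - tumor.positions[tu_map[f]]
                )
                t = f * interval
                if d <= radius + _EPS:
                    if open_start is None:
                        open_start = t
                    last_in = t
                else:
                    if open_start is not None:
                        events.append(
                            _make_event(nk, tumor, open_start, last_in, False)
                        )
                        open_start = None
            if open_start is not None:
                censored = last_in >= movie_end - interval / 2
                events.append(_make_event(nk, tumor, open_start, last_in, censored))
    events.sort(key=lambda e: (e.start_time, e.nk_track_id, e.tumor_id))
    for i, e in enumerate(events):
        e.event_id = f"event_{i:04d}"
    return events


def _make_event(nk, tumor, start, end, censored) -> ContactEvent:
    return ContactEvent(
        event_id="",
        nk_track_id=nk.track_id,
        tumor_id=tumor.track_id,
        start_time=float(start),
        end_time=float(end),
        censored=bool(censored),
    )


def hit_rate(events: Sequence[ContactEvent], tumor_tracks: Sequence[Track]) -> float:
    """Total hit count divided by summed tumor observation time (hits/min)."""
    total_time = sum(tr.duration for tr in tumor_tracks)
    if total_time <= 0:
        raise ValueError("total tumor observation time must be positive")
    return len(events) / total_time


def classify_mover(
    event: ContactEvent,
    nk_track: Track,
    min_precontact_frames: int = 4,
) -> str:
    """Classify the contacting NK cell as crawling, flowing or indeterminate.

    Crawling: tracked for more than *min_precontact_frames* samples strictly
    before contact start. Flowing: the track's first sample coincides with
    the contact start (the cell appeared already in contact). Anything in
    between is indeterminate.
    """
    if nk_track.track_id != event.nk_track_id:
        raise ValueError(
            f"event {event.event_id} references track {event.nk_track_id}, "
            f"got {nk_track.track_id}"
        )
    n_pre = int(np.sum(nk_track.times < event.start_time - _EPS))
    if n_pre == 0:
        return "flowing"
    if n_pre > min_precontact_frames:
        return "crawling"
    return "indeterminate"


# ---------------------------------------------------------------------------
# reporter-event detection


def detect_activation(
    series: ReporterSeries,
    contact_time: float,
    rise_fraction: float = 0.30,
    window: float = 3.0,
) -> tuple[bool, float | None]:
    """Threshold-crossing event detection on a reporter series.

    The baseline is the mean over ``series.baseline_window`` minutes before
    *contact_time* (needs >= 2 samples). The cell is activated if any sample
    in ``(contact_time, contact_time + window]`` exceeds
    ``(1 + rise_fraction) * baseline``; the lag is the first crossing time
    minus *contact_time*.
    """
    t, v = series.times, series.values
    base_mask = (t >= contact_time - series.baseline_window - _EPS) & (
        t < contact_time - _EPS
    )
    if base_mask.sum() < 2:
        raise ValueError(
            f"baseline window before t={contact_time} min contains "
            f"{int(base_mask.sum())} samples; need at least 2"
        )
    baseline = float(v[base_mask].mean())
    threshold = (1.0 + rise_fraction) * baseline
    post = (t > contact_time - _EPS) & (t <= contact_time + window + _EPS)
    crossing = post & (v > threshold)
    if not crossing.any():
        return False, None
    lag = float(t[crossing][0] - contact_time)
    return True, max(lag, 0.0)


# ---------------------------------------------------------------------------
# outcome table


def _proportion(k: int, n: int) -> dict:
    """Exact binomial point estimate with Clopper-Pearson 95% interval.
    Zero denominator yields a None-valued sentinel record."""
    if n == 0:
        return {"k": 0, "n": 0, "p": None, "ci95": None}
    test = binomtest(k, n)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return {"k": k, "n": n, "p": k / n, "ci95": [float(ci.low), float(ci.high)]}


@dataclass
class OutcomeTable:
    """Contact-outcome counts, conditional probabilities and median lags."""

    n_contacts: int
    p_erk_given_contact: dict
    p_ca_given_erk: dict
    p_ca_given_contact: dict
    p_caspase_given_contact: dict
    p_death_given_contact: dict
    mover_share_of_influx: dict  # crawling/flowing/indeterminate fractions
    median_lags_min: dict  # per outcome, None when no lag observed

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def contact_outcome_table(events: Sequence[ContactEvent]) -> OutcomeTable:
    """Summarize outcomes over contact events.

    Proportions carry exact binomial 95% intervals. The mover-class shares
    are computed over calcium-influx events and sum to 1 when any exist.
    """
    events = list(events)
    if not events:
        raise ValueError("contact_outcome_table needs at least one event")
    n = len(events)
    erk = [e for e in events if e.erk_activated]
    ca = [e for e in events if e.ca_influx]
    caspase = [e for e in events if e.caspase]
    died = [e for e in events if e.tumor_died]
    ca_given_erk = [e for e in erk if e.ca_influx]

    shares: dict[str, float | None]
    if ca:
        shares = {
            cls: sum(1 for e in ca if e.mover_class == cls) / len(ca)
            for cls in ("crawling", "flowing", "indeterminate")
        }
    else:
        shares = {"crawling": None, "flowing": None, "indeterminate": None}

    def median_lag(evts, attr):
        lags = [getattr(e, attr) for e in evts if getattr(e, attr) is not None]
        return float(np.median(lags)) if lags else None

    return OutcomeTable(
        n_contacts=n,
        p_erk_given_contact=_proportion(len(erk), n),
        p_ca_given_erk=_proportion(len(ca_given_erk), len(erk)),
        p_ca_given_contact=_proportion(len(ca), n),
        p_caspase_given_contact=_proportion(len(caspase), n),
        p_death_given_contact=_proportion(len(died), n),
        mover_share_of_influx=shares,
        median_lags_min={
            "erk": median_lag(erk, "erk_lag"),
            "ca": median_lag(ca, "ca_lag"),
            "caspase": median_lag(caspase, "caspase_lag"),
        },
    )


# ---------------------------------------------------------------------------
# I/O

_EVENT_COLUMNS = [
    "event_id",
    "nk_track_id",
    "tumor_id",
    "t_start_min",
    "t_end_min",
    "mover_class",
    "erk",
    "erk_lag_min",
    "ca",
    "ca_lag_min",
    "caspase",
    "caspase_lag_min",
    "death",
    "censored",
]


def write_events(events: Sequence[ContactEvent], path: str | Path) -> None:
    rows = [
        (
            e.event_id,
            e.nk_track_id,
            e.tumor_id,
            e.start_time,
            e.end_time,
            e.mover_class,
            int(e.erk_activated),
            e.erk_lag,
            int(e.ca_influx),
            e.ca_lag,
            int(e.caspase),
            e.caspase_lag,
            int(e.tumor_died),
            int(e.censored),
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[ContactEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} is missing columns {sorted(missing)}")

    def lag(x):
        return None if pd.isna(x) else float(x)

    return [
        ContactEvent(
            event_id=str(r.event_id),
            nk_track_id=str(r.nk_track_id),
            tumor_id=str(r.tumor_id),
            start_time=float(r.t_start_min),
            end_time=float(r.t_end_min),
            mover_class=str(r.mover_class),
            erk_activated=bool(r.erk),
            erk_lag=lag(r.erk_lag_min),
            ca_influx=bool(r.ca),
            ca_lag=lag(r.ca_lag_min),
            caspase=bool(r.caspase),
            caspase_lag=lag(r.caspase_lag_min),
            tumor_died=bool(r.death),
            censored=bool(r.censored),
        )
        for r in df.itertuples()
    ]


def write_reporters(series: Sequence[ReporterSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            rows.append((s.cell_id, s.channel, t, v))
    pd.DataFrame(rows, columns=["cell_id", "channel", "t_min", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_reporters(path: str | Path) -> list[ReporterSeries]:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "channel", "t_min", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reporter table {path} is missing columns {sorted(missing)}")
    out = []
    for (cell_id, channel), g in df.groupby(["cell_id", "channel"], sort=False):
        g = g.sort_values("t_min")
        out.append(
            ReporterSeries(
                cell_id=str(cell_id),
                channel=str(channel),
                times=g["t_min"].to_numpy(dtype=float),
                values=g["value"].to_numpy(dtype=float),
            )
        )
    return out
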