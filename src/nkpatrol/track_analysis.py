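"""Motion statistics on 3D cell trajectories from intravital imaging.

Covers nearest-neighbor detection linking, instantaneous speed, ensemble
mean squared displacement (MSD), anomalous-diffusion exponent fitting and
crawl-duration statistics. The canonical sampling is one volume every 30 s
(0.5 min); positions are in micrometres, times in minutes.

Sub-diffusive motion (MSD ~ tau^alpha with alpha < 1) is the signature of
NK cells whose migration is confined to the capillary network; alpha is
estimated by a nonlinear least-squares power-law fit on the linear scale,
initialized from a log-log linear fit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Detection",
    "Track",
    "MSDCurve",
    "DiffusionFit",
    "CrawlStats",
    "FitError",
    "link_detections",
    "instantaneous_speed",
    "ensemble_msd",
    "fit_msd_powerlaw",
    "crawl_duration_stats",
    "read_tracks",
    "write_tracks",
]

DEFAULT_FRAME_INTERVAL = 0.5  # min, i.e. one volume every 30 s


@dataclass(frozen=True)
class Detection:
    """A single localized cell at one frame."""

    frame_index: int
    time: float  # min
    position: np.ndarray  # (3,) µm
    class_label: str = "nk"  # "nk" or "tumor"
    intensity: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")


@dataclass
class Track:
    """One cell's time-ordered 3D trajectory.

    ``times`` are minutes, ``positions`` µm with shape ``(n, 3)``. ``gaps``
    lists frame indices at which the cell was not detected inside the track's
    span. ``censored`` flags tracks truncated by the end of the movie.
    """

    track_id: str
    cell_class: str
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    gaps: list[int] = field(default_factory=list)
    censored: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) < 2:
            raise ValueError("a track needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Track duration in minutes (last minus first sample time)."""
        return float(self.times[-1] - self.times[0])

    def frame_indices(self) -> np.ndarray:
        """Sample frame indices relative to the track start."""
        rel = (self.times - self.times[0]) / self.frame_interval
        idx = np.rint(rel).astype(int)
        if not np.allclose(rel, idx, atol=1e-6):
            raise ValueError(
                f"track {self.track_id}: sample times are not on the "
                f"{self.frame_interval}-min frame grid"
            )
        return idx


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the log-log fallback estimate."""

    def __init__(self, message: str, fallback_alpha: float, fallback_prefactor: float):
        super().__init__(message)
        self.fallback_alpha = fallback_alpha
        self.fallback_prefactor = fallback_prefactor


# ---------------------------------------------------------------------------
# linking


def link_detections(
    detections: Sequence[Detection],
    max_distance: float = 30.0,
    max_frame_gap: int = 2,
) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Detections are processed frame by frame in input order; each links to the
    nearest unclaimed track end within ``max_distance`` µm, searching back up
    to ``max_frame_gap`` frames (so at most ``max_frame_gap - 1`` consecutive
    missing frames are bridged). Equidistant candidates resolve to the
    earlier-created track; competing detections resolve by input order.
    Unlinked detections seed new tracks; single-sample tracks are discarded.
    """
    if not detections:
        return []
    frames = np.array([d.frame_index for d in detections])
    order = np.argsort(frames, kind="stable")
    _check_frame_timing(detections)

    # candidate track state: list of dicts with samples and last frame/pos
    open_tracks: list[dict] = []
    for idx in order:
        det = detections[idx]
        best = None
        best_dist = np.inf
        for tr in open_tracks:
            d_frames = det.frame_index - tr["last_frame"]
            if d_frames < 1 or d_frames > max_frame_gap:
                continue
            if tr["claimed_frame"] == det.frame_index:
                continue
            if tr["cell_class"] != det.class_label:
                continue
            dist = float(np.linalg.norm(det.position - tr["last_pos"]))
            if dist <= max_distance and dist < best_dist:
                best = tr
                best_dist = dist
        if best is None:
            open_tracks.append(
                {
                    "cell_class": det.class_label,
                    "samples": [(det.time, det.position)],
                    "frames": [det.frame_index],
                    "last_frame": det.frame_index,
                    "last_pos": det.position,
                    "claimed_frame": det.frame_index,
                    "gaps": [],
                }
            )
        else:
            gap = det.frame_index - best["last_frame"]
            if gap > 1:
                best["gaps"].extend(range(best["last_frame"] + 1, det.frame_index))
            best["samples"].append((det.time, det.position))
            best["frames"].append(det.frame_index)
            best["last_frame"] = det.frame_index
            best["last_pos"] = det.position
            best["claimed_frame"] = det.frame_index

    interval = _frame_interval(detections)
    tracks = []
    for i, tr in enumerate(open_tracks):
        if len(tr["samples"]) < 2:
            continue
        times = np.array([t for t, _ in tr["samples"]])
        positions = np.vstack([p for _, p in tr["samples"]])
        tracks.append(
            Track(
                track_id=f"track_{i:04d}",
                cell_class=tr["cell_class"],
                times=times,
                positions=positions,
                frame_interval=interval,
                gaps=tr["gaps"],
            )
        )
    return tracks


def _frame_interval(detections: Sequence[Detection]) -> float:
    pairs = {}
    for d in detections:
        pairs.setdefault(d.frame_index, d.time)
    frames = sorted(pairs)
    if len(frames) < 2:
        return DEFAULT_FRAME_INTERVAL
    diffs = [
        (pairs[b] - pairs[a]) / (b - a) for a, b in zip(frames[:-1], frames[1:])
    ]
    return float(diffs[0])


def _check_frame_timing(detections: Sequence[Detection]) -> None:
    """All detections at one frame index must share one time stamp, and the
    time per frame must be constant across the movie."""
    times_by_frame: dict[int, float] = {}
    for d in detections:
        t = times_by_frame.setdefault(d.frame_index, d.time)
        if abs(t - d.time) > 1e-9:
            raise ValueError(
                f"inconsistent frame timing at frame {d.frame_index}: "
                f"{t} vs {d.time} min"
            )
    frames = sorted(times_by_frame)
    if len(frames) >= 3:
        rates = np.array(
            [
                (times_by_frame[b] - times_by_frame[a]) / (b - a)
                for a, b in zip(frames[:-1], frames[1:])
            ]
        )
        if not np.allclose(rates, rates[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame interval is not constant across the movie")


# ---------------------------------------------------------------------------
# speed


def instantaneous_speed(track: Track, dt: float = 0.5) -> np.ndarray:
    """Speeds ``|r(t) - r(t - dt)| / dt`` in µm/min for all pairs separated by
    exactly *dt*, skipping pairs that bridge a detection gap.

    *dt* must be an integer multiple of the track's frame interval.
    """
    steps = dt / track.frame_interval
    k = int(round(steps))
    if k < 1 or abs(steps - k) > 1e-6:
        raise ValueError(
            f"dt={dt} min is not a positive integer multiple of the frame "
            f"interval {track.frame_interval} min"
        )
    idx = track.frame_indices()
    # pairs at sample offsets whose frame-index difference is exactly k and
    # with no missing frame in between (consecutive samples span the gap)
    speeds = []
    pos = track.positions
    for i in range(len(idx)):
        j = i + k
        if j >= len(idx):
            break
        if idx[j] - idx[i] != k:
            continue
        speeds.append(np.linalg.norm(pos[j] - pos[i]) / dt)
    return np.asarray(speeds, dtype=float)


# ---------------------------------------------------------------------------
# MSD


@dataclass
class MSDCurve:
    """Ensemble MSD: ``lags`` in minutes, ``msd_values`` in µm²,
    ``n_cells_per_lag`` contributing tracks and ``n_pairs_per_lag``
    contributing displacement pairs."""

    lags: np.ndarray
    msd_values: np.ndarray
    n_cells_per_lag: np.ndarray
    n_pairs_per_lag: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lags_min": [float(x) for x in self.lags],
            "msd_um2": [float(x) for x in self.msd_values],
            "n_cells_per_lag": [int(x) for x in self.n_cells_per_lag],
            "n_pairs_per_lag": [int(x) for x in self.n_pairs_per_lag],
        }


def ensemble_msd(
    tracks: Sequence[Track],
    max_lag: float = 50.0,
    origins: Literal["all", "first"] = "all",
) -> MSDCurve:
    """Ensemble mean squared displacement over cells.

    ``origins="all"`` averages over every available time origin within each
    track (variance reduction); ``origins="first"`` uses only each track's
    first sample as origin, the literal reading of
    ``MSD(tau) = <|r_i(tau) - r_i(0)|^2>_i``. Lags run on the frame grid up
    to *max_lag* minutes; lags with no contributing pair are omitted.
    Lag 0 is included with MSD exactly 0.
    """
    if not tracks:
        raise ValueError("ensemble_msd needs at least one track")
    interval = tracks[0].frame_interval
    for tr in tracks:
        if abs(tr.frame_interval - interval) > 1e-9:
            raise ValueError("tracks have mismatched frame intervals")
    max_k = int(math.floor(max_lag / interval + 1e-9))
    sums = np.zeros(max_k + 1)
    pair_counts = np.zeros(max_k + 1, dtype=int)
    cell_counts = np.zeros(max_k + 1, dtype=int)
    for tr in tracks:
        idx = tr.frame_indices()
        n_frames = idx[-1] + 1
        grid = np.full((n_frames, 3), np.nan)
        grid[idx] = tr.positions
        present = ~np.isnan(grid[:, 0])
        for k in range(1, min(max_k, n_frames - 1) + 1):
            if origins == "first":
                if not present[0] or k >= n_frames or not present[k]:
                    continue
                disp = grid[k] - grid[0]
                sq = np.array([disp @ disp])
            else:
                ok = present[:-k] & present[k:]
                if not ok.any():
                    continue
                diff = grid[k:][ok] - grid[:-k][ok]
                sq = np.einsum("ij,ij->i", diff, diff)
            sums[k] += sq.sum()
            pair_counts[k] += len(sq)
            cell_counts[k] += 1
    keep = np.concatenate(([0], np.nonzero(pair_counts[1:])[0] + 1))
    lags = keep * interval
    msd = np.zeros(len(keep))
    nz = pair_counts[keep] > 0
    msd[nz] = sums[keep][nz] / pair_counts[keep][nz]
    cells0 = cell_counts[keep].copy()
    cells0[0] = len(tracks)
    return MSDCurve(
        lags=lags,
        msd_values=msd,
        n_cells_per_lag=cells0,
        n_pairs_per_lag=pair_counts[keep],
    )


@dataclass
class DiffusionFit:
    """Power-law MSD fit ``MSD(tau) = prefactor * tau^alpha``."""

    alpha: float
    prefactor: float  # µm²/min^alpha
    fit_window: tuple[float, float]  # min
    residual_norm: float  # µm²

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "prefactor_um2_per_min_alpha": self.prefactor,
            "fit_window_min": list(self.fit_window),
            "residual_norm_um2": self.residual_norm,
        }


def fit_msd_powerlaw(
    curve: MSDCurve, fit_window: tuple[float, float] | None = None
) -> DiffusionFit:
    """Fit ``MSD(tau) = c * tau^alpha`` by nonlinear least squares on the
    linear scale, initialized from a log-log linear fit.

    *fit_window* restricts the lags used (inclusive, minutes); by default all
    positive-MSD lags enter. Needs at least three positive-MSD lags.
    """
    lags = np.asarray(curve.lags, dtype=float)
    msd = np.asarray(curve.msd_values, dtype=float)
    mask = (lags > 0) & (msd > 0)
    if fit_window is not None:
        lo, hi = fit_window
        mask &= (lags >= lo) & (lags <= hi)
    x, y = lags[mask], msd[mask]
    if len(x) < 3:
        raise ValueError("need at least three lags with positive MSD in the window")
    window = (float(x.min()), float(x.max()))
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    alpha0, c0 = float(slope), float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda t, c, a: c * t**a, x, y, p0=[c0, alpha0], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(
            f"power-law MSD fit did not converge: {exc}",
            fallback_alpha=alpha0,
            fallback_prefactor=c0,
        ) from exc
    c_hat, a_hat = float(popt[0]), float(popt[1])
    resid = float(np.linalg.norm(y - c_hat * x**a_hat))
    return DiffusionFit(
        alpha=a_hat, prefactor=c_hat, fit_window=window, residual_norm=resid
    )


# ---------------------------------------------------------------------------
# crawl durations


@dataclass
class CrawlStats:
    """Summary of crawl-episode durations (minutes).

    ``rate_per_min`` is the exponential maximum-likelihood rate 1/mean over
    uncensored durations; ``ln2 / rate_per_min`` estimates the median of the
    underlying exponential. Right-censored episodes (track alive at movie
    end) are counted but excluded from the median and MLE by default.
    """

    n: int
    n_censored: int
    median_min: float
    mean_min: float
    rate_per_min: float
    exp_median_min: float  # ln2 / rate: exponential-model median
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_censored": self.n_censored,
            "median_min": self.median_min,
            "mean_min": self.mean_min,
            "rate_per_min": self.rate_per_min,
            "exp_median_min": self.exp_median_min,
            "hist_edges_min": [float(x) for x in self.hist_edges],
            "hist_counts": [int(x) for x in self.hist_counts],
        }


def crawl_duration_stats(
    tracks: Iterable[Track],
    bin_width: float = 1.0,
    include_censored: bool = False,
    detection_floor: float | None = None,
) -> CrawlStats:
    """Median, exponential-rate MLE and histogram of crawl durations.

    Exponential crawl dwell implies a survival curve ``2^(-t/median)``; the
    MLE of the rate is 1/mean, so ``ln2 / rate`` estimates the median too.
    Right-censored episodes (track alive at movie end) are excluded from the
    estimates by default. *detection_floor* corrects the MLE for left
    truncation when stalls shorter than the sampling interval are
    unobservable: with 30-s frames, episodes below half a frame never yield
    a two-sample track, so the rate MLE becomes ``1 / (mean - floor)``
    (memorylessness of the exponential).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("crawl_duration_stats needs at least one track")
    durations = np.array([tr.duration for tr in tracks])
    censored = np.array([tr.censored for tr in tracks], dtype=bool)
    observed = durations if include_censored else durations[~censored]
    if len(observed) == 0:
        raise ValueError("all durations are censored")
    mean = float(np.mean(observed))
    shifted = mean - (detection_floor or 0.0)
    rate = 1.0 / shifted if shifted > 0 else math.inf
    edges = np.arange(0.0, durations.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(observed, bins=edges)
    return CrawlStats(
        n=len(durations),
        n_censored=int(censored.sum()),
        median_min=float(np.median(observed)),
        mean_min=mean,
        rate_per_min=rate,
        exp_median_min=math.log(2.0) / rate if math.isfinite(rate) else 0.0,
        hist_edges=edges,
        hist_counts=counts,
    )


# ---------------------------------------------------------------------------
# I/O: long-format delimited table


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks as a long-format TSV with columns
    track_id, cell_class, frame, t_min, x_um, y_um, z_um."""
    rows = []
    for tr in tracks:
        frames = tr.frame_indices()
        for f, t, (x, y, z) in zip(frames, tr.times, tr.positions):
            rows.append((tr.track_id, tr.cell_class, int(f), t, x, y, z))
    df = pd.DataFrame(
        rows, columns=["track_id", "cell_class", "frame", "t_min", "x_um", "y_um", "z_um"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read tracks written by :func:`write_tracks`.

    The frame interval is inferred from the time stamps; a track whose last
    sample falls on the movie's final frame is marked censored.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"track_id", "cell_class", "frame", "t_min", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track table {path} is missing columns {sorted(missing)}")
    if len(df) == 0:
        return []
    interval = _infer_interval(df)
    movie_end = float(df["t_min"].max())
    tracks = []
    for track_id, g in df.groupby("track_id", sort=False):
        g = g.sort_values("t_min")
        if len(g) < 2:
            continue
        times = g["t_min"].to_numpy(dtype=float)
        frames = g["frame"].to_numpy(dtype=int)
        gaps = sorted(set(range(frames[0], frames[-1] + 1)) - set(frames))
        tracks.append(
            Track(
                track_id=str(track_id),
                cell_class=str(g["cell_class"].iloc[0]),
                times=times,
                positions=g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                frame_interval=interval,
                gaps=gaps,
                censored=bool(times[-1] >= movie_end - interval / 2),
            )
        )
    return tracks


def _infer_interval(df: pd.DataFrame) -> float:
    by_frame = df.groupby("frame")["t_min"].first().sort_index()
    if len(by_frame) < 2:
        return DEFAULT_FRAME_INTERVAL
    frames = by_frame.index.to_numpy()
    times = by_frame.to_numpy()
    return float((times[1:] - times[:-1])[0] / (frames[1:] - frames[:-1])[0])
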