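"""End-to-end pipeline: simulate -> analyze -> parameter cascade -> report.

The full run pools several simulated intravital movies, recomputes every
measured quantity from the emitted tables with the analysis modules (speed,
MSD exponent, crawl durations, hit rate, outcome probabilities, BLI decay),
feeds the measured hit rate / kill probability / crawl speed into the
kinetic cascade alongside the anatomical constants, and emits a consistency
report comparing the three melanoma half-life estimates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import bli_decay, encounter_stats, kinetic_model, synthetic, track_analysis

__all__ = ["run_simulate", "run_analyze", "run_params", "run_report",
           "run_full_pipeline"]


def _json_sanitize(obj):
    """Make numbers JSON-safe: inf -> 'inf', numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


def _write_json(data: dict, path: Path) -> None:
    path.write_text(json.dumps(_json_sanitize(data), indent=1) + "\n")


def _config_hash(config: synthetic.SimConfig) -> str:
    payload = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _prefixed(result: synthetic.PatrolResult, prefix: str) -> synthetic.PatrolResult:
    """Rename track and event ids with a per-movie prefix so pooled tables
    stay unambiguous."""
    for tr in result.nk_tracks + result.tumor_tracks:
        tr.track_id = prefix + tr.track_id
    for ev in result.events:
        ev.event_id = prefix + ev.event_id
        ev.nk_track_id = prefix + ev.nk_track_id
        ev.tumor_id = prefix + ev.tumor_id
    gt = result.ground_truth
    gt.survival_times_min = {prefix + k: v for k, v in gt.survival_times_min.items()}
    for c in gt.contacts:
        c["tumor_id"] = prefix + c["tumor_id"]
        c["nk_track_id"] = prefix + c["nk_track_id"]
    return result


def run_simulate(
    config: synthetic.SimConfig, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Simulate ``config.n_movies`` movies plus BLI curves; write all tables.

    Outputs: tracks.tsv, events.tsv, reporters.tsv, bli.tsv,
    ground_truth.json, manifest.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(base_seed).spawn(config.n_movies + 2)

    nk_tracks, tumor_tracks, events, reporters = [], [], [], []
    gt_all = {"movies": [], "config": config.as_dict(), "seed": base_seed}
    for m in range(config.n_movies):
        movie_seed = int(children[m].generate_state(1)[0] % (2**31))
        network = synthetic.build_capillary_network(config, seed=movie_seed)
        result = synthetic.simulate_patrol(network, config, seed=movie_seed + 1)
        result = _prefixed(result, f"m{m:02d}_")
        reporters.extend(
            synthetic.generate_reporter_series(result.events, config, movie_seed + 2)
        )
        nk_tracks.extend(result.nk_tracks)
        tumor_tracks.extend(result.tumor_tracks)
        events.extend(result.events)
        gt = result.ground_truth
        gt_all["movies"].append(
            {
                "seed": movie_seed,
                "survival_times_min": gt.survival_times_min,
                "n_contacts": len(gt.contacts),
                "contacts": gt.contacts,
            }
        )

    bli_seed = int(children[-1].generate_state(1)[0] % (2**31))
    bli_series = synthetic.simulate_bli(config, seed=bli_seed)

    track_analysis.write_tracks(nk_tracks + tumor_tracks, out_dir / "tracks.tsv")
    encounter_stats.write_events(events, out_dir / "events.tsv")
    encounter_stats.write_reporters(reporters, out_dir / "reporters.tsv")
    bli_decay.write_bli(bli_series, out_dir / "bli.tsv")
    _write_json(gt_all, out_dir / "ground_truth.json")
    manifest = {
        "stage": "simulate",
        "seed": base_seed,
        "config_hash": _config_hash(config),
        "outputs": ["tracks.tsv", "events.tsv", "reporters.tsv", "bli.tsv",
                    "ground_truth.json"],
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    _write_json(manifest, out_dir / "manifest.json")
    return manifest


def run_analyze(in_dir: str | Path, out_dir: str | Path | None = None) -> dict:
    """Recompute all measured quantities from the simulated (or imported)
    tables; write analysis.json."""
    in_dir = Path(in_dir)
    out_dir = Path(out_dir) if out_dir is not None else in_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    tracks = track_analysis.read_tracks(in_dir / "tracks.tsv")
    events = encounter_stats.read_events(in_dir / "events.tsv")
    bli_series = bli_decay.read_bli(in_dir / "bli.tsv")

    nk_tracks = [t for t in tracks if t.cell_class == "nk"]
    tumor_tracks = [t for t in tracks if t.cell_class == "tumor"]
    flowing_ids = {e.nk_track_id for e in events if e.mover_class == "flowing"}
    crawl_tracks = [t for t in nk_tracks if t.track_id not in flowing_ids]

    speeds = np.concatenate(
        [track_analysis.instantaneous_speed(t, dt=t.frame_interval)
         for t in crawl_tracks]
    ) if crawl_tracks else np.array([])
    msd = track_analysis.ensemble_msd(crawl_tracks, max_lag=50.0)
    try:
        fit = track_analysis.fit_msd_powerlaw(msd)
        fit_dict = fit.to_dict()
    except (ValueError, track_analysis.FitError) as exc:
        fit_dict = {"error": str(exc)}
    crawl_stats = track_analysis.crawl_duration_stats(crawl_tracks)
    rate = encounter_stats.hit_rate(events, tumor_tracks)
    outcomes = encounter_stats.contact_outcome_table(events)

    exponents, doublings, nadirs = [], [], []
    for s in bli_series:
        norm = bli_decay.normalize_bli(s)
        exponents.append(bli_decay.fit_decay_powerlaw(norm))
        nadir = bli_decay.nadir_time(norm)
        nadirs.append(nadir)
        growth = bli_decay.doubling_time(norm, window=(nadir, norm.times[-1]))
        if math.isfinite(growth):
            doublings.append(growth)
    b_mean = float(np.mean(exponents))

    analysis = {
        "n_nk_tracks": len(nk_tracks),
        "n_crawl_tracks": len(crawl_tracks),
        "n_tumor_tracks": len(tumor_tracks),
        "mean_speed_um_min": float(speeds.mean()) if len(speeds) else None,
        "median_speed_um_min": float(np.median(speeds)) if len(speeds) else None,
        "msd_fit": fit_dict,
        "crawl_stats": crawl_stats.to_dict(),
        "hit_rate_per_min": rate,
        "outcomes": outcomes.to_dict(),
        "bli": {
            "decay_exponent_mean": b_mean,
            "decay_exponents": [float(b) for b in exponents],
            "half_life_min": bli_decay.half_life_at(b_mean, t_ref=4.0),
            "nadir_hours_mean": float(np.mean(nadirs)),
            "doubling_time_hours_mean": (
                float(np.mean(doublings)) if doublings else "inf"
            ),
        },
    }
    _write_json(analysis, out_dir / "analysis.json")
    return analysis


def run_params(
    params_path: str | Path | None = None, out_dir: str | Path = "."
) -> dict:
    """Evaluate the kinetic cascade; write params_report.tsv and params.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    measured = (
        kinetic_model.table1_params()
        if params_path is None
        else kinetic_model.load_measured_params(params_path)
    )
    derived = kinetic_model.compute_derived_parameters(measured)
    (out_dir / "params_report.tsv").write_text(
        kinetic_model.render_report(measured, derived)
    )
    payload = {
        "measured": dataclasses.asdict(measured),
        "derived": derived.as_dict(),
    }
    _write_json(payload, out_dir / "params.json")
    return payload


def run_report(
    analysis_dir: str | Path,
    out_dir: str | Path | None = None,
    params_path: str | Path | None = None,
    tolerance: float = 0.25,
) -> dict:
    """Consistency report: plug the measured hit rate, kill probability and
    crawl speed into the cascade (anatomy constants from the parameter file)
    and compare the half-life predictions with the BLI-derived one."""
    analysis_dir = Path(analysis_dir)
    out_dir = Path(out_dir) if out_dir is not None else analysis_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = json.loads((analysis_dir / "analysis.json").read_text())

    base = (
        kinetic_model.table1_params()
        if params_path is None
        else kinetic_model.load_measured_params(params_path)
    )
    p_kill = analysis["outcomes"]["p_ca_given_contact"]["p"]
    if p_kill is None:
        raise ValueError("no contacts in analysis; cannot estimate kill probability")
    measured = dataclasses.replace(
        base,
        observed_hit_rate=float(analysis["hit_rate_per_min"]),
        kill_probability=float(p_kill),
        nk_crawl_speed=float(analysis["mean_speed_um_min"]) * 1e-6,
    )
    derived = kinetic_model.compute_derived_parameters(measured)
    report = kinetic_model.consistency_report(
        derived, bli_half_life=float(analysis["bli"]["half_life_min"]),
        tolerance=tolerance,
    )
    (out_dir / "params_report.tsv").write_text(
        kinetic_model.render_report(measured, derived)
    )
    payload = {
        "measured": dataclasses.asdict(measured),
        "derived": derived.as_dict(),
        "consistency": report.as_dict(),
    }
    _write_json(payload, out_dir / "consistency.json")
    return payload


def run_full_pipeline(
    config: synthetic.SimConfig | str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
    params_path: str | Path | None = None,
) -> dict:
    """simulate -> analyze -> cascade -> consistency report, one call.

    Returns the consistency payload; all intermediate tables land in
    *out_dir*. Stage failures propagate with the stage name attached.
    """
    if config is None:
        config = synthetic.SimConfig()
    elif not isinstance(config, synthetic.SimConfig):
        config = synthetic.load_sim_config(config)
    out_dir = Path(out_dir)
    stages = [
        ("simulate", lambda: run_simulate(config, out_dir, seed=seed)),
        ("analyze", lambda: run_analyze(out_dir)),
        ("params", lambda: run_params(params_path, out_dir / "table")),
        ("report", lambda: run_report(out_dir, params_path=params_path)),
    ]
    result: dict = {}
    for name, fn in stages:
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return result
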