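"""Seeded generators for every input the analysis pipeline consumes.

The centrepiece is an agent-based simulator of NK-cell "stall-crawl-jump"
patrolling on a synthetic pulmonary capillary network: a random geometric
graph confined to a thin imaging slab stands in for the capillary bed (the
downstream statistics depend only on encounter rates and path constraints,
not on true anatomy). NK agents arrive as a Poisson stream, adhere, crawl
along edges at a configured speed for an exponentially distributed dwell
time, then jump back into the flow. Static tumor agents lodge on the
network; contacts fire by the 10-µm proximity rule and outcomes (ERK
activation, Ca²⁺ influx / kill, caspase) are Bernoulli draws with
log-normal lags. Dead tumors stop being observable.

Also provided: exact fractional-Gaussian-motion tracks with a known
anomalous exponent, an event-level killing-kinetics simulator with a
closed-form exponential survival law, per-cell reporter time series, and
two-phase bioluminescence curves (power-law decay, then exponential
regrowth).

Every generator is deterministic per (seed, config).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import yaml
from scipy.linalg import cholesky, toeplitz

from .encounter_stats import ContactEvent, ReporterSeries, classify_mover, detect_hits
from .track_analysis import Track

__all__ = [
    "NetworkConfig",
    "NKConfig",
    "TumorConfig",
    "OutcomeConfig",
    "BLIConfig",
    "SimConfig",
    "GroundTruth",
    "PatrolResult",
    "load_sim_config",
    "build_capillary_network",
    "total_edge_length",
    "simulate_patrol",
    "simulate_killing_kinetics",
    "fractional_tracks",
    "generate_reporter_series",
    "simulate_bli",
]


# ---------------------------------------------------------------------------
# configuration

# log-normal sigma putting the quartiles at [0.5x, 2x] the median
DEFAULT_LAG_SIGMA = math.log(2.0) / 0.6745


@dataclass
class NetworkConfig:
    """Random geometric capillary graph inside the imaging slab."""

    n_nodes: int = 60
    connection_radius_um: float = 90.0
    capillary_radius_um: float = 3.4


@dataclass
class NKConfig:
    """NK agent behaviour.

    When ``flow_arrival_rate_cells_min`` is None, the adhering arrival rate
    is derived so the steady-state crawler count equals
    ``target_linear_density_cells_mm`` times the network length — i.e. the
    simulator is parameterized from the measured NK linear density on the
    capillaries (2.1 cells/mm).
    """

    crawl_speed_mean_um_min: float = 4.8
    crawl_speed_sd_um_min: float = 0.5
    crawl_dwell_median_min: float = 30.0
    target_linear_density_cells_mm: float = 2.1
    flow_arrival_rate_cells_min: float | None = None
    adhesion_probability: float = 0.37
    flow_contact_rate_per_min: float = 0.0005  # flowing contacts per tumor-min


@dataclass
class TumorConfig:
    """Lodged tumor cells.

    Random lodging sites keep ``clearance_um`` of free space to every
    non-host capillary segment and to the host segment's junctions, so each
    tumor's 10-µm proximity ball spans a single vessel segment — matching
    the imaging picture of a cell plugging one capillary. Set the clearance
    to 0 for fully random lodging.
    """

    count: int = 5
    lodging_positions_um: list | None = None  # list of [x, y, z]; None = random
    clearance_um: float = 12.0


@dataclass
class OutcomeConfig:
    """Bernoulli contact outcomes and log-normal lag distributions.

    Defaults follow the measured event fractions: ERK activation in 68% of
    contacts, Ca²⁺ influx (the kill surrogate) in 43/60 of ERK-activated
    contacts, caspase reported in ~18% of contacts overall. ERK lags are
    truncated at the 3-min activation window, matching the within-3-min
    definition under which the 68% was counted.
    """

    p_erk_given_contact: float = 0.68
    p_kill_given_erk: float = 43.0 / 60.0
    p_caspase_given_kill: float = 0.37
    erk_lag_median_min: float = 1.5
    erk_lag_max_min: float = 3.0
    ca_lag_median_min: float = 4.0
    caspase_lag_median_min: float = 26.0
    lag_sigma: float = DEFAULT_LAG_SIGMA
    reporter_step_amplitude: float = 0.40  # ERK step, above the 0.30 threshold
    reporter_surge_amplitude: float = 3.0  # Ca²⁺ surge pulse
    reporter_noise_cv: float = 0.05


@dataclass
class BLIConfig:
    """Two-phase bioluminescence curve: t^-b decay to the nadir, then
    exponential regrowth with the configured doubling time."""

    decay_exponent: float = 1.45
    nadir_hours: float = 24.0
    growth_doubling_hours: float = 24.0
    noise_cv: float = 0.10
    n_animals: int = 4
    time_grid_hours: list = field(
        default_factory=lambda: [1.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0, 96.0]
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated intravital movie."""

    fov_side_um: float = 500.0
    slab_depth_um: float = 25.0
    frame_interval_min: float = 0.5
    duration_min: float = 120.0
    n_movies: int = 60  # pooled independent movies in the full pipeline
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    nk: NKConfig = field(default_factory=NKConfig)
    tumor: TumorConfig = field(default_factory=TumorConfig)
    outcomes: OutcomeConfig = field(default_factory=OutcomeConfig)
    bli: BLIConfig = field(default_factory=BLIConfig)

    def __post_init__(self):
        for name in ("fov_side_um", "slab_depth_um", "frame_interval_min",
                     "duration_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_erk_given_contact", "p_kill_given_erk",
                     "p_caspase_given_kill"):
            p = getattr(self.outcomes, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcomes.{name} must be in [0, 1]")
        if not 0.0 <= self.nk.adhesion_probability <= 1.0:
            raise ValueError("nk.adhesion_probability must be in [0, 1]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "network": NetworkConfig,
    "nk": NKConfig,
    "tumor": TumorConfig,
    "outcomes": OutcomeConfig,
    "bli": BLIConfig,
}


def load_sim_config(source: str | Path | dict) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file or nested mapping.

    Unknown keys raise ``ValueError`` naming the offending key.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for key, value in raw.items():
        if key not in top_fields:
            raise ValueError(f"unknown config key {key!r}")
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            for sub in value or {}:
                if sub not in sub_fields:
                    raise ValueError(f"unknown config key {key + '.' + sub!r}")
            kwargs[key] = cls(**(value or {}))
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# capillary network


def build_capillary_network(
    config: SimConfig, seed: int | None = None, prune_dead_ends: bool = True
) -> nx.Graph:
    """Random geometric graph in the FOV slab standing in for the capillary
    mesh.

    By default the 2-core of the largest connected component is retained:
    capillaries form closed loops, so the synthetic network has no dead-end
    branches either. Node attribute ``pos`` holds the 3D position (µm); edge
    attribute ``length`` the Euclidean edge length.
    """
    net = config.network
    if net.n_nodes < 2:
        raise ValueError("network.n_nodes must be >= 2")
    if net.connection_radius_um <= 0:
        raise ValueError("network.connection_radius_um must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pos = rng.uniform(
        low=[0.0, 0.0, 0.0],
        high=[config.fov_side_um, config.fov_side_um, config.slab_depth_um],
        size=(net.n_nodes, 3),
    )
    graph = nx.random_geometric_graph(
        net.n_nodes, net.connection_radius_um, pos={i: pos[i] for i in range(net.n_nodes)}
    )
    if graph.number_of_edges() == 0:
        raise ValueError(
            "degenerate capillary geometry: no edges (connection radius too small)"
        )
    if prune_dead_ends:
        graph = nx.k_core(graph, 2)
        if graph.number_of_nodes() == 0:
            raise ValueError(
                "degenerate capillary geometry: no closed loops (network too sparse)"
            )
    components = nx.connected_components(graph)
    largest = max(components, key=len)
    graph = graph.subgraph(largest).copy()
    for u, v in graph.edges:
        graph.edges[u, v]["length"] = float(
            np.linalg.norm(np.asarray(graph.nodes[u]["pos"]) - np.asarray(graph.nodes[v]["pos"]))
        )
    if graph.number_of_edges() == 0:
        raise ValueError("degenerate capillary geometry: no edges after pruning")
    return graph


def total_edge_length(graph: nx.Graph) -> float:
    """Total capillary length of the network in µm."""
    return float(sum(d["length"] for _, _, d in graph.edges(data=True)))


def _edge_arrays(graph: nx.Graph):
    edges = list(graph.edges)
    lengths = np.array([graph.edges[e]["length"] for e in edges])
    return edges, lengths


def _point_on_network(graph, edges, lengths, rng):
    """Uniform random point on the network (length-weighted edge choice).
    Returns (position, edge index, fractional coordinate)."""
    i = int(rng.choice(len(edges), p=lengths / lengths.sum()))
    u, v = edges[i]
    s = rng.uniform(0.0, 1.0)
    pu = np.asarray(graph.nodes[u]["pos"])
    pv = np.asarray(graph.nodes[v]["pos"])
    return (1 - s) * pu + s * pv, i, s


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _lodging_sites(graph, edges, lengths, rng, count, clearance, max_tries=2000):
    """Tumor lodging positions whose proximity ball spans one vessel segment.

    Rejection-samples points on the network that keep *clearance* µm of free
    space to every non-host edge, to the host edge's junction nodes and to
    previously placed tumors. Falls back to unconstrained points if the
    network is too crowded to satisfy the clearance.
    """
    node_pos = {n: np.asarray(graph.nodes[n]["pos"]) for n in graph.nodes}
    placed: list[np.ndarray] = []
    for _ in range(count):
        best = None
        for _ in range(max_tries):
            p, i, _s = _point_on_network(graph, edges, lengths, rng)
            hu, hv = edges[i]
            if min(np.linalg.norm(p - node_pos[hu]),
                   np.linalg.norm(p - node_pos[hv])) <= clearance:
                continue
            if any(np.linalg.norm(p - q) <= 2 * clearance for q in placed):
                continue
            ok = True
            for j, (u, v) in enumerate(edges):
                if j == i:
                    continue
                if _point_segment_distance(p, node_pos[u], node_pos[v]) <= clearance:
                    ok = False
                    break
            if ok:
                best = p
                break
        if best is None:  # crowded network: accept an unconstrained point
            best = _point_on_network(graph, edges, lengths, rng)[0]
        placed.append(best)
    return placed


# ---------------------------------------------------------------------------
# patrol simulation


@dataclass
class GroundTruth:
    """Generator-side record of what actually happened.

    ``survival_times_min`` maps tumor id to the continuous kill time, or
    None for tumors alive at movie end (right-censored). ``contacts`` lists
    every retained contact with its outcome draws.
    """

    contacts: list  # dicts: tumor_id, nk_track_id, time, mover, erk, ca, death
    survival_times_min: dict
    crawl_dwell_true_min: list  # continuous dwell draws behind emitted crawls
    crawl_speeds_um_min: list  # per-agent speed draws
    config: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PatrolResult:
    nk_tracks: list
    tumor_tracks: list
    events: list
    ground_truth: GroundTruth
    network: nx.Graph


def simulate_patrol(
    network: nx.Graph, config: SimConfig, seed: int | None = None
) -> PatrolResult:
    """Simulate one intravital movie of NK patrolling and tumor killing.

    Crawling agents arrive on the frame grid as a Poisson stream whose rate
    is calibrated to the target NK linear density, crawl along the network
    as a persistent random walk, and detach after an exponential dwell.
    Flowing contacts appear already within the hit radius of a tumor and
    last a single frame pair. Contacts are detected by the 10-µm rule on the
    emitted tracks; outcomes are Bernoulli draws, one kill per tumor, and
    tumor tracks are truncated at the kill time.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dt = config.frame_interval_min
    n_frames = int(round(config.duration_min / dt)) + 1
    last_t = (n_frames - 1) * dt
    edges, lengths = _edge_arrays(network)
    network_length = float(lengths.sum())
    nk_cfg = config.nk

    mean_dwell = nk_cfg.crawl_dwell_median_min / math.log(2.0)
    if nk_cfg.flow_arrival_rate_cells_min is None:
        n_steady = nk_cfg.target_linear_density_cells_mm * network_length / 1000.0
        adhering_rate = n_steady / mean_dwell
    else:
        adhering_rate = (
            nk_cfg.flow_arrival_rate_cells_min * nk_cfg.adhesion_probability
        )

    # --- tumors (placed first: they plug their capillary segment) ----------
    if config.tumor.lodging_positions_um is not None:
        tumor_pos = [
            np.asarray(p, dtype=float) for p in config.tumor.lodging_positions_um
        ]
    else:
        tumor_pos = _lodging_sites(
            network, edges, lengths, rng, config.tumor.count,
            config.tumor.clearance_um,
        )

    def _start_clear_of_tumors():
        # a lodged tumor occludes its segment, so NK cells cannot stall
        # inside its proximity ball
        for _ in range(200):
            p, i, s = _point_on_network(network, edges, lengths, rng)
            if all(np.linalg.norm(p - q) > 10.0 for q in tumor_pos):
                return i, s
        return i, s

    # --- crawling episodes -------------------------------------------------
    # The movie samples a stationary patrolling process: the network starts
    # populated at the steady-state crawler count, with residual dwells that
    # are again exponential (memorylessness), and new adherent arrivals come
    # in as a Poisson stream on the frame grid.
    nk_tracks: list[Track] = []
    dwell_true: list[float] = []
    speeds: list[float] = []
    agent = 0
    n_steady = adhering_rate * mean_dwell
    episodes = [(0, float(rng.exponential(mean_dwell)))
                for _ in range(rng.poisson(n_steady))]
    for f in range(n_frames):
        episodes.extend(
            (f, float(rng.exponential(mean_dwell)))
            for _ in range(rng.poisson(adhering_rate * dt))
        )
    for f, dwell in episodes:
        speed = max(0.5, rng.normal(nk_cfg.crawl_speed_mean_um_min,
                                    nk_cfg.crawl_speed_sd_um_min))
        n_ep = int(round(dwell / dt))
        censored = f + n_ep > n_frames - 1
        n_ep = min(n_ep, n_frames - 1 - f)
        dwell_true.append(dwell)
        if n_ep < 1:
            continue  # stall shorter than one frame: not resolvable
        speeds.append(speed)
        edge_i, edge_s = _start_clear_of_tumors()
        positions = _crawl_path(
            network, edges, lengths, rng, speed * dt, n_ep + 1,
            start=(edge_i, edge_s),
        )
        times = (f + np.arange(n_ep + 1)) * dt
        nk_tracks.append(
            Track(
                track_id=f"nk_{agent:04d}",
                cell_class="nk",
                times=times,
                positions=positions,
                frame_interval=dt,
                censored=censored,
            )
        )
        agent += 1

    tumor_tracks = [
        Track(
            track_id=f"tumor_{j:03d}",
            cell_class="tumor",
            times=np.arange(n_frames) * dt,
            positions=np.tile(p, (n_frames, 1)),
            frame_interval=dt,
            censored=True,
        )
        for j, p in enumerate(tumor_pos)
    ]

    # --- flowing contacts --------------------------------------------------
    for j, p in enumerate(tumor_pos):
        for f in range(n_frames - 1):
            if rng.random() < nk_cfg.flow_contact_rate_per_min * dt:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = p + 5.0 * direction
                nk_tracks.append(
                    Track(
                        track_id=f"nk_{agent:04d}",
                        cell_class="nk",
                        times=np.array([f, f + 1]) * dt,
                        positions=np.vstack([pos, pos]),
                        frame_interval=dt,
                    )
                )
                agent += 1

    # --- contacts and outcomes ---------------------------------------------
    raw_events = detect_hits(nk_tracks, tumor_tracks, radius=10.0)
    nk_by_id = {tr.track_id: tr for tr in nk_tracks}
    out = config.outcomes
    death_time: dict[str, float | None] = {tr.track_id: None for tr in tumor_tracks}
    events: list[ContactEvent] = []
    gt_contacts: list[dict] = []
    for ev in raw_events:
        dtime = death_time[ev.tumor_id]
        if dtime is not None and ev.start_time > dtime:
            continue
        ev.mover_class = classify_mover(ev, nk_by_id[ev.nk_track_id])
        if rng.random() < out.p_erk_given_contact:
            ev.erk_activated = True
            ev.erk_lag = _lognormal_lag(
                rng, out.erk_lag_median_min, out.lag_sigma, out.erk_lag_max_min
            )
            if dtime is None and rng.random() < out.p_kill_given_erk:
                ev.ca_influx = True
                ev.ca_lag = _lognormal_lag(rng, out.ca_lag_median_min, out.lag_sigma)
                ev.tumor_died = True
                death_time[ev.tumor_id] = ev.start_time + ev.ca_lag
                if rng.random() < out.p_caspase_given_kill:
                    ev.caspase = True
                    ev.caspase_lag = _lognormal_lag(
                        rng, out.caspase_lag_median_min, out.lag_sigma
                    )
        events.append(ev)
        gt_contacts.append(
            {
                "tumor_id": ev.tumor_id,
                "nk_track_id": ev.nk_track_id,
                "time_min": ev.start_time,
                "mover_class": ev.mover_class,
                "erk": ev.erk_activated,
                "ca_influx": ev.ca_influx,
                "death": ev.tumor_died,
            }
        )

    # --- truncate killed tumors; drop events past the death frame ----------
    for j, tr in enumerate(tumor_tracks):
        dtime = death_time[tr.track_id]
        if dtime is None:
            continue
        last_frame = max(1, int(math.floor(dtime / dt + 1e-9)))
        last_frame = min(last_frame, n_frames - 1)
        tumor_tracks[j] = Track(
            track_id=tr.track_id,
            cell_class="tumor",
            times=tr.times[: last_frame + 1],
            positions=tr.positions[: last_frame + 1],
            frame_interval=dt,
            censored=False,
        )
    kept = []
    for ev in events:
        dtime = death_time[ev.tumor_id]
        if dtime is not None:
            tumor_end = tumor_tracks[
                [t.track_id for t in tumor_tracks].index(ev.tumor_id)
            ].times[-1]
            if ev.start_time > tumor_end:
                continue
            ev.end_time = min(ev.end_time, float(tumor_end))
            ev.censored = ev.censored and death_time[ev.tumor_id] is None
        kept.append(ev)
    events = kept
    for i, ev in enumerate(events):
        ev.event_id = f"event_{i:04d}"

    ground_truth = GroundTruth(
        contacts=gt_contacts,
        survival_times_min={k: v for k, v in death_time.items()},
        crawl_dwell_true_min=dwell_true,
        crawl_speeds_um_min=speeds,
        config=config.as_dict(),
    )
    return PatrolResult(
        nk_tracks=nk_tracks,
        tumor_tracks=tumor_tracks,
        events=events,
        ground_truth=ground_truth,
        network=network,
    )


def _lognormal_lag(rng, median: float, sigma: float, upper: float | None = None) -> float:
    """Log-normal lag with the given median; optionally truncated above."""
    for _ in range(1000):
        lag = float(rng.lognormal(math.log(median), sigma))
        if upper is None or lag <= upper:
            return lag
    return min(median, upper if upper is not None else median)


def _crawl_path(
    graph, edges, lengths, rng, step_um, n_samples, start=None
) -> np.ndarray:
    """Persistent random walk along network edges at fixed step length."""
    if start is None:
        i = int(rng.choice(len(edges), p=lengths / lengths.sum()))
        frac = rng.uniform(0.0, 1.0)
    else:
        i, frac = start
    u, v = edges[i]
    if rng.random() < 0.5:
        u, v = v, u
        frac = 1.0 - frac
    s = frac * graph.edges[u, v]["length"]
    positions = np.empty((n_samples, 3))
    pu = np.asarray(graph.nodes[u]["pos"])
    pv = np.asarray(graph.nodes[v]["pos"])
    edge_len = graph.edges[u, v]["length"]
    positions[0] = pu + (pv - pu) * (s / edge_len)
    for k in range(1, n_samples):
        d = step_um
        while d > 0:
            remaining = edge_len - s
            if d < remaining:
                s += d
                d = 0.0
            else:
                d -= remaining
                # arrived at v: pick the next edge, avoiding an immediate
                # U-turn when the node has other neighbours
                neighbours = [w for w in graph.neighbors(v)]
                choices = [w for w in neighbours if w != u] or neighbours
                w = choices[rng.integers(len(choices))]
                u, v = v, w
                pu = np.asarray(graph.nodes[u]["pos"])
                pv = np.asarray(graph.nodes[v]["pos"])
                edge_len = graph.edges[u, v]["length"]
                s = 0.0
        positions[k] = pu + (pv - pu) * (s / edge_len)
    return positions


# ---------------------------------------------------------------------------
# event-level killing kinetics


def simulate_killing_kinetics(
    contact_rate: float,
    p_death: float,
    n_tumors: int,
    duration: float,
    seed: int,
    frame_interval: float = 0.5,
) -> tuple[list[ContactEvent], list[Track], np.ndarray, np.ndarray]:
    """Poisson contacts x Bernoulli kill, with a closed-form survival law.

    Each tumor receives contacts as a homogeneous Poisson process with rate
    *contact_rate* (per minute); each contact kills with probability
    *p_death*, so the survival time is exponential with rate
    ``contact_rate * p_death``. Observation stops at the kill or at
    *duration*. Returns (events, tumor_tracks, survival_times, censored);
    censored tumors carry ``survival_time == duration``.
    """
    if contact_rate <= 0:
        raise ValueError("contact_rate must be positive")
    if not 0.0 <= p_death <= 1.0:
        raise ValueError("p_death must be in [0, 1]")
    rng = np.random.default_rng(seed)
    events: list[ContactEvent] = []
    tumor_tracks: list[Track] = []
    survival = np.empty(n_tumors)
    censored = np.zeros(n_tumors, dtype=bool)
    eid = 0
    for j in range(n_tumors):
        t = 0.0
        death: float | None = None
        while death is None:
            t += rng.exponential(1.0 / contact_rate)
            if t > duration:
                break
            kill = rng.random() < p_death
            events.append(
                ContactEvent(
                    event_id=f"event_{eid:05d}",
                    nk_track_id=f"nk_virtual_{eid:05d}",
                    tumor_id=f"tumor_{j:04d}",
                    start_time=t,
                    end_time=t,
                    mover_class="crawling",
                    ca_influx=kill,
                    tumor_died=kill,
                )
            )
            eid += 1
            if kill:
                death = t
        if death is None:
            survival[j] = duration
            censored[j] = True
            obs_end = duration
        else:
            survival[j] = death
            obs_end = death
        times = np.array([0.0, obs_end])
        tumor_tracks.append(
            Track(
                track_id=f"tumor_{j:04d}",
                cell_class="tumor",
                times=times if obs_end > 0 else np.array([0.0, frame_interval]),
                positions=np.zeros((2, 3)),
                frame_interval=frame_interval,
                censored=bool(censored[j]),
            )
        )
    return events, tumor_tracks, survival, censored


# ---------------------------------------------------------------------------
# fractional tracks with a known anomalous exponent


def fractional_tracks(
    alpha: float,
    n_tracks: int,
    n_steps: int,
    dt: float = 0.5,
    step_um: float = 1.0,
    seed: int = 0,
    cell_class: str = "nk",
) -> list[Track]:
    """3D fractional Brownian motion tracks with MSD ~ tau^alpha exactly.

    Exact fractional Gaussian noise via Cholesky factorization of the
    increment covariance (Hurst index H = alpha/2); each spatial dimension
    is an independent fBm, so the ensemble MSD is
    ``3 * step_um**2 * (tau/dt)**alpha``.
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError("alpha must be in (0, 2]")
    hurst = alpha / 2.0
    rng = np.random.default_rng(seed)
    k = np.arange(n_steps, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    cov = toeplitz(gamma) + 1e-12 * np.eye(n_steps)
    chol = cholesky(cov, lower=True)
    noise = rng.standard_normal(size=(n_tracks, 3, n_steps))
    increments = step_um * np.einsum("st,nct->ncs", chol, noise)
    positions = np.concatenate(
        [np.zeros((n_tracks, 3, 1)), np.cumsum(increments, axis=2)], axis=2
    )
    times = np.arange(n_steps + 1) * dt
    return [
        Track(
            track_id=f"fbm_{i:05d}",
            cell_class=cell_class,
            times=times,
            positions=positions[i].T,
            frame_interval=dt,
        )
        for i in range(n_tracks)
    ]


# ---------------------------------------------------------------------------
# reporter series


def generate_reporter_series(
    events: Sequence[ContactEvent],
    config: SimConfig,
    seed: int,
    duration: float | None = None,
) -> list[ReporterSeries]:
    """Per-cell reporter series with outcomes injected at the drawn lags.

    The NK cell of each contact gets a ``fret_ratio`` (ERK) series, the
    tumor a ``gcamp`` series. Baseline is 1 with multiplicative Gaussian
    noise; ERK activation adds a sustained step, Ca²⁺ influx a decaying
    surge pulse. Only the first event per cell is rendered.
    """
    rng = np.random.default_rng(seed)
    dt = config.frame_interval_min
    out = config.outcomes
    if duration is None:
        duration = config.duration_min
    series: list[ReporterSeries] = []
    seen: set[tuple[str, str]] = set()
    for ev in events:
        t0 = max(0.0, ev.start_time - 4.0)
        t1 = min(duration, ev.start_time + 12.0)
        times = np.arange(round(t0 / dt), round(t1 / dt) + 1) * dt
        if len(times) < 2:
            continue
        if ("nk", ev.nk_track_id) not in seen:
            seen.add(("nk", ev.nk_track_id))
            values = np.ones(len(times))
            if ev.erk_activated and ev.erk_lag is not None:
                values[times >= ev.start_time + ev.erk_lag - 1e-9] += (
                    out.reporter_step_amplitude
                )
            values *= 1.0 + out.reporter_noise_cv * rng.standard_normal(len(times))
            series.append(
                ReporterSeries(
                    cell_id=ev.nk_track_id,
                    channel="fret_ratio",
                    times=times,
                    values=np.clip(values, 1e-6, None),
                )
            )
        if ("tumor", ev.tumor_id) not in seen:
            seen.add(("tumor", ev.tumor_id))
            values = np.ones(len(times))
            if ev.ca_influx and ev.ca_lag is not None:
                onset = ev.start_time + ev.ca_lag
                after = times >= onset - 1e-9
                decay = np.exp(-(times[after] - onset) / 3.0)
                values[after] += out.reporter_surge_amplitude * decay
            values *= 1.0 + out.reporter_noise_cv * rng.standard_normal(len(times))
            series.append(
                ReporterSeries(
                    cell_id=ev.tumor_id,
                    channel="gcamp",
                    times=times,
                    values=np.clip(values, 1e-6, None),
                )
            )
    return series


# ---------------------------------------------------------------------------
# bioluminescence


def simulate_bli(config: SimConfig, seed: int | None = None) -> list:
    """Two-phase BLI curves on the standard time grid, normalized shape.

    Power-law decay ``t^-b`` to the nadir, then exponential regrowth with
    the configured doubling time; multiplicative log-normal noise with the
    configured CV (exact curve at CV 0).
    """
    from .bli_decay import BLISeries

    bli = config.bli
    if bli.decay_exponent <= 0 or bli.growth_doubling_hours <= 0:
        raise ValueError("decay exponent and doubling time must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.asarray(bli.time_grid_hours, dtype=float)
    nadir_value = bli.nadir_hours ** (-bli.decay_exponent)
    clean = np.where(
        t <= bli.nadir_hours,
        t ** (-bli.decay_exponent),
        nadir_value * 2.0 ** ((t - bli.nadir_hours) / bli.growth_doubling_hours),
    )
    sigma = math.sqrt(math.log(1.0 + bli.noise_cv**2))
    out = []
    for a in range(bli.n_animals):
        noise = (
            np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(t)))
            if bli.noise_cv > 0
            else np.ones(len(t))
        )
        out.append(
            BLISeries(
                animal_id=f"mouse_{a:02d}",
                times=t,
                intensities=clean * noise,
                group="control",
            )
        )
    return out
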