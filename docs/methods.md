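# Methods

`nkpatrol` models the earliest, intravascular phase of lung metastasis:
natural killer (NK) cells patrolling the pulmonary capillary bed encounter
and kill tumor cells that have just lodged there. The package implements
the quantitative chain from raw cell trajectories and reporter time series
to a predicted tumor half-life, and a synthetic-data generator that
produces every input with known ground truth.

## The kinetic cascade

The core model treats tumor killing as a first-order process. A lodged
tumor cell is contacted ("hit", defined as an NK cell coming within 10 µm,
center-to-center) at a rate `k_hit` (hits/min), and each contact kills with
probability `p_kill`, so the tumor population decays at rate
`k = p_kill * k_hit` and the tumor half-life is `t_1/2 = ln2 / k`.

`k_hit` is obtained in two independent ways:

1. **Observed**: hit events counted in intravital movies divided by the
   summed tumor observation time (`hit_rate`).
2. **Predicted from crawling**: NK cells crawl along capillaries at speed
   `v` with linear density `rho` (cells per unit capillary length), so a
   static target is encountered at `k_hit = rho * v` — the 1D flux of
   crawlers into the target's proximity window.

`rho` itself comes from a cascade of measured quantities: NK density in the
imaged volume (cells per field of view / (FOV area × imaging-plane
thickness, taken as one NK diameter)) scaled to the whole lung volume, then
divided by the total capillary length. The same cascade yields the NK flux
through the lung (cardiac output × blood NK concentration), the steady-state
NK residence half-life (`ln2 * N_lung / influx`, about 1.6 min — most NK
cells transit without stalling), and the per-capillary NK flow rate
(blood concentration × capillary volumetric flow, the latter from platelet
speed × lumen cross-section).

All arithmetic is carried in full floating precision; published versions of
this table round intermediates, which drifts terminal values by a few
percent (the crawl-predicted melanoma half-life is the worst case, ~3%).
Two defects in commonly printed versions of these parameters are handled
explicitly and are not configurable:

* an FOV area printed with a positive exponent (`2.5E+07 m²`) for a
  0.5 × 0.5 mm² field is treated as a sign typo (`2.5e-7 m²`);
* a printed capillary flow rate of `1.60e-12 m³/min` is inconsistent with
  the stated formula `Plt_speed·π·Cp_r²` (≈ `2.07e-12`); the formula value
  is used because the downstream per-capillary NK flow rate (0.11
  cells/min) is only consistent with it.

Units: SI metres and minutes internally. Parameter files must carry a unit
suffix on every key (`capillary_radius_um: 3.4`); conversion happens once
at the boundary. Zero rates produce an explicit infinite-half-life
sentinel, serialized as the string `"inf"`, never a division error.

The consistency check compares the two trajectory-derived half-lives with
the bioluminescence-derived one as ratios, with a configurable tolerance
defaulting to ±25% — the precision one can claim for parameters measured
from in vivo imaging.

## Trajectory statistics

Tracks are time-ordered 3D positions sampled every 30 s (0.5 min).
Detection linking is greedy nearest-neighbour with a 30-µm max step,
searching back up to 2 frames; gaps are recorded and never interpolated
(interpolation would bias speeds low). Instantaneous speed uses pairs
exactly Δt apart, skipping pairs that bridge a gap.

The ensemble MSD averages squared displacements over cells; by default it
also averages over all time origins within each track (variance reduction,
valid for the stationary-increment processes simulated here), with a
`origins="first"` mode that implements the literal
`MSD(τ) = ⟨|r_i(τ) − r_i(0)|²⟩_i` definition. The anomalous exponent α in
`MSD(τ) = c·τ^α` is fitted by nonlinear least squares on the linear scale
(matching common practice in the field), initialized from a log-log linear
fit; the log-log estimate is carried as the fallback when the nonlinear
solver fails. α < 1 indicates sub-diffusive, confinement-limited migration.
The fit window defaults to all lags up to 50 min and is configurable.

Crawl-episode durations are summarized by the sample median and an
exponential maximum-likelihood rate (1/mean). Durations truncated by the
movie end are flagged censored and excluded by default. Because a 30-s
frame interval cannot resolve stalls shorter than half a frame (such
episodes never produce the two detections a track requires), the MLE
supports a `detection_floor` correction: for exponential dwells observed
only above a floor, memorylessness gives `rate = 1/(mean − floor)`. With
the floor at dt/2 this removes the ~+20% bias that frame quantization
otherwise puts on a 2.5-min median.

## Contact and outcome statistics

A hit opens when the NK–tumor distance first reaches 10 µm (boundary
inclusive) and closes at the first observed frame beyond it; re-entry is a
new hit; episodes still open at the movie end are flagged censored.
Contacting NK cells are classified *crawling* when tracked for more than 4
frames (2 min) before contact, *flowing* when already in contact at first
appearance, otherwise *indeterminate*.

Reporter events use a threshold rule: activation is a rise of more than 30%
over the pre-contact baseline (mean of the 2 min before contact) within 3
min of contact. The same machinery serves ERK (FRET/CFP ratio), Ca²⁺
(GCaMP intensity, the surrogate for a lethal perforin/granzyme hit) and
caspase (inverted FRET) series; the 30% threshold is quantitative only for
ERK — for the other channels it is a configurable assumption. Outcome
proportions (activation given contact, influx given activation, etc.)
carry exact Clopper–Pearson 95% intervals; zero denominators yield
explicit `None` sentinels rather than NaNs.

## Bioluminescence decay

Whole-animal luminescence (BLI) tracks viable tumor burden. Series are
normalized to the 1-h post-injection reference (log-log interpolated
between bracketing samples when no sample falls at 1 h exactly — linear in
log t vs log I, hence exact on a power-law segment, which is the curve
family being fitted). The decay phase over 1–12 h follows `BLI(t) = t^-b`;
b is fitted by least squares on the linear scale with a log-log
initializer. Because power-law decay slows with time, the half-life is
quoted at a reference time, default 4 h, as the curve-halving time
`t_ref·(2^(1/b) − 1)` (b = 1.45 gives 147 min); an instantaneous-rate mode
`ln2·t_ref/b` is also exposed. The regrowth phase after the nadir
(typically 24 h) is fitted log-linearly; a non-positive slope returns an
infinite-doubling-time sentinel.

## The synthetic-data generator

The generator emulates one intravital movie: a 500 × 500 × 25 µm slab
sampled every 30 s for 120 min.

**Capillary geometry** is a random geometric graph over uniform points in
the slab (default 60 nodes, 90-µm connection radius, ~8-mm total length).
Only the 2-core of the largest component is kept: real capillaries form
closed loops, and dead-end branches would force U-turning walkers into
artifactual repeat encounters. The graph is a geometry stand-in — the
statistics the pipeline computes depend on encounter rates and path
constraints, not on true anatomy.

**NK agents.** Patrolling is stationary when a movie starts, so the
network is pre-populated with a Poisson number of crawlers at the
steady-state count, with residual dwells drawn from the same exponential
(memorylessness makes this the exact stationary residual); fresh adherent
arrivals then come in as a Poisson stream on the frame grid. The
steady-state count is calibrated from the measured NK linear density on
capillaries (2.1 cells/mm) times the realized network length — i.e. the
simulator is parameterized from the same measured table as the cascade.
Each crawler moves as a persistent random walk along edges at a per-agent
speed (normal, mean 4.8 µm/min, sd 0.5) for an exponential dwell
(default median 30 min, the tumor-present condition; 2.5 and 5 min presets
correspond to tumor-free imaging), then detaches ("jumps"). Episodes
shorter than one frame are unobservable and emit no track, mirroring the
instrument.

**Tumors** are static points on the network. Default lodging sites keep
12 µm of clearance to every other capillary segment and to junctions, so
each tumor's 10-µm proximity ball spans a single vessel segment — the
geometry the imaging shows for a cell plugging one capillary, and the
regime in which the `rho·v` flux law holds (a ball spanning k segments
multiplies the encounter rate by ~k, a random-geometric-graph artifact
with no anatomical counterpart). A lodged tumor occludes its segment, so
crawl episodes never start inside its ball. With this geometry the
emergent hit rate reproduces the `rho·v` prediction to within a few
percent, with honest contributions from re-entries and walk-in starts.

**Contacts and outcomes.** Contacts are detected on the emitted tracks by
the same 10-µm rule the analysis uses. Outcomes are Bernoulli draws: ERK
activation with p = 0.68 per contact; given activation, a lethal Ca²⁺
influx with p = 43/60; given a kill, caspase becomes detectable with
p = 0.37 (chosen so caspase appears in ~18% of contacts overall). Lags are
log-normal with σ = ln2/0.6745 ≈ 1.03, placing quartiles at [0.5×, 2×] the
median (medians: ERK 1.5 min truncated at the 3-min window it is defined
by, Ca²⁺ 4 min, caspase 26 min). One kill per tumor; the tumor track is
truncated at the kill time and later contacts with it are discarded.
Flowing contacts (an NK cell appearing already within the hit radius)
arrive as a small per-tumor Poisson stream (default 5 × 10⁻⁴/min).

**Reporter series** are baseline-1 with multiplicative Gaussian noise
(CV 5%); activation adds a sustained +40% step (above the 30% threshold),
influx a decaying +300% surge.

**BLI curves** are piecewise: `t^-1.45` to the 24-h nadir, then exponential
regrowth with a 24-h doubling time, log-normal multiplicative noise
(CV 10%), sampled at {1, 4, 8, 12, 24, 48, 72, 96} h.

**Killing-kinetics simulator.** Where a check requires a generator contact
rate known in closed form (the hit-rate estimator and the survival law),
an event-level simulator draws per-tumor contacts as a homogeneous Poisson
process and kills as Bernoulli thinning, making survival exactly
exponential with rate `contact_rate × p_death`. The spatial simulator's
emergent rate is a measured, not a configured, quantity, so it cannot
serve as an exact oracle.

**Sub-diffusive tracks** with a known exponent come from exact fractional
Gaussian noise (Cholesky factorization of the fGn covariance, Hurst index
α/2, three independent components), giving `MSD(τ) ∝ τ^α` exactly in
expectation. The network walk is locally persistent and only mildly
confined at the 500-µm FOV scale, so its emergent α is near 1; fBm is the
controlled generator for exponent-recovery checks.

## What the generator does and does not emulate

It reproduces: frame quantization and censoring, linking-style tracks,
stationary patrolling at a measured density, 10-µm contact logic, Bernoulli
outcomes with lag distributions, two-phase BLI shapes. It does not
reproduce: real vascular anatomy and flow mechanics, segmentation and
tracking errors, photobleaching or motion artifacts, NK heterogeneity
(DNAM-1⁺/⁻ subsets), the time-dependent loss of tumor-cell ligands
(killing probabilities are constant in time), or thrombosis. Passing
round-trip tests therefore demonstrates estimator correctness under the
stated model, not robustness to real imaging artifacts.

## Problem sizes and numerical choices

The default full pipeline pools 60 simulated movies (5 tumors each,
120 min), a cohort giving ~250–300 contacts so the hit rate and kill
probability are estimated to a few percent; exponent-recovery checks use
500 tracks of 120 frames; rate/survival checks pool 20 seeds of 50 tumors.
Bioluminescence summaries use 4-animal groups (6 in the reproduction
script, the upper end of typical per-group cohorts).

Ties in linking resolve to the earlier-created track and earlier detection
index (deterministic). Distances are center-to-center; the hit boundary is
inclusive at exactly 10 µm. Every generator consumes a single
`numpy.random.default_rng(seed)` stream; identical (seed, config) gives
bit-identical outputs. Nonlinear fits that fail raise an error carrying
the log-log fallback estimate rather than returning silently.

## Known limitations

* The cascade propagates no uncertainties; it is a point-value model.
* The crawl/stall distinction is merged into a single adhesion episode
  (no separate stalled-state dwell distribution is available to emulate).
* Hit detection treats tumor cells as points; a cell-surface distance
  definition would shift the effective contact radius.
* The mover classification of a crawler that begins its episode already
  near a tumor is genuinely ambiguous and is labelled flowing or
  indeterminate, as a human annotator would.
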