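"""Kinetic parameter cascade for NK-cell surveillance of the lung capillary bed.

Starting from a small set of measured anatomical and intravital-imaging
quantities (blood volume, cardiac output, NK-cell blood count, field-of-view
NK counts, crawl speed, observed hit rate, kill probability), the cascade
derives the NK-cell flux through the lung, the steady-state NK residence
half-life, the encounter rate between crawling NK cells and a lodged tumor
cell, and two independent predictions of the melanoma half-life:

* ``melanoma_half_life_obs`` — from the directly observed hit rate,
  ``ln2 / (kill_probability * observed_hit_rate)``;
* ``melanoma_half_life_crawl`` — from first principles, using the NK linear
  density on the capillaries times the crawl speed as the hit rate.

Both can then be compared against a bioluminescence-derived half-life with
:func:`consistency_report`.

All quantities are SI metres and minutes internally; parameter files carry
explicit unit suffixes (see :mod:`nkpatrol.units`). The cascade is evaluated
in full floating precision with no intermediate rounding — published tables
round intermediates, which drifts terminal values by a few percent.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .units import allowed_units, convert

__all__ = [
    "MeasuredParams",
    "DerivedParams",
    "ConsistencyReport",
    "compute_derived_parameters",
    "half_life_from_rate",
    "consistency_report",
    "load_measured_params",
    "table1_params",
    "render_report",
]

#: sentinel for "no decay": a zero rate gives an infinite half-life,
#: serialized as the string "inf"
INFINITE_HALF_LIFE = math.inf

# quantity kind of each measured field, used by the parameter-file loader
_FIELD_KINDS = {
    "blood_volume": "volume",
    "lung_volume": "volume",
    "cardiac_output": "flow",
    "total_capillary_length": "length",
    "fov_area": "area",
    "platelet_speed": "speed",
    "capillary_radius": "length",
    "nk_diameter": "length",
    "nk_blood_conc": "concentration",
    "nk_per_fov": "count",
    "nk_crawl_speed": "speed",
    "observed_hit_rate": "rate",
    "kill_probability": "dimensionless",
}


@dataclass(frozen=True)
class MeasuredParams:
    """Measured inputs to the cascade, SI metres/minutes.

    ``observed_hit_rate`` is hits per minute of tumor observation;
    ``kill_probability`` is the probability that a contact kills the tumor
    cell (estimated from the calcium-influx fraction of contacts).
    """

    blood_volume: float  # m^3
    lung_volume: float  # m^3
    cardiac_output: float  # m^3/min
    total_capillary_length: float  # m
    fov_area: float  # m^2
    platelet_speed: float  # m/min, proxy for capillary plasma flow speed
    capillary_radius: float  # m
    nk_diameter: float  # m, used as imaging-slab thickness
    nk_blood_conc: float  # cells/m^3
    nk_per_fov: float  # cells per field of view
    nk_crawl_speed: float  # m/min
    observed_hit_rate: float  # hits/min per tumor; may be 0
    kill_probability: float  # in [0, 1]

    def __post_init__(self) -> None:
        strictly_positive = [
            "blood_volume",
            "lung_volume",
            "cardiac_output",
            "total_capillary_length",
            "fov_area",
            "platelet_speed",
            "capillary_radius",
            "nk_diameter",
            "nk_blood_conc",
            "nk_per_fov",
            "nk_crawl_speed",
        ]
        for name in strictly_positive:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (math.isfinite(self.observed_hit_rate) and self.observed_hit_rate >= 0):
            raise ValueError(
                f"observed_hit_rate must be >= 0, got {self.observed_hit_rate!r}"
            )
        if not (0.0 <= self.kill_probability <= 1.0):
            raise ValueError(
                f"kill_probability must be in [0, 1], got {self.kill_probability!r}"
            )


@dataclass(frozen=True)
class DerivedParams:
    """Outputs of the cascade, SI metres/minutes.

    Half-lives are ``math.inf`` when the corresponding decay rate is zero.
    """

    capillary_flow_rate: float  # m^3/min
    nk_whole_blood: float  # cells
    nk_density_lung: float  # cells/m^3
    nk_total_lung: float  # cells
    nk_influx: float  # cells/min
    nk_decay_const: float  # 1/min
    nk_half_life: float  # min
    nk_flow_rate_capillary: float  # cells/min through one capillary
    nk_linear_density: float  # cells/m of capillary
    crawl_hit_rate: float  # hits/min per tumor, from density x speed
    melanoma_decay_obs: float  # 1/min
    melanoma_half_life_obs: float  # min
    melanoma_decay_crawl: float  # 1/min
    melanoma_half_life_crawl: float  # min

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def half_life_from_rate(rate: float) -> float:
    """Half-life ``ln2 / rate`` in minutes for a first-order decay rate (1/min).

    A zero rate means no decay and returns the infinite sentinel.
    """
    if not math.isfinite(rate) or rate < 0:
        raise ValueError(f"decay rate must be >= 0 and finite, got {rate!r}")
    if rate == 0:
        return INFINITE_HALF_LIFE
    return math.log(2.0) / rate


def compute_derived_parameters(measured: MeasuredParams) -> DerivedParams:
    """Evaluate the full parameter cascade in full floating precision."""
    m = measured
    capillary_flow_rate = m.platelet_speed * math.pi * m.capillary_radius**2
    nk_whole_blood = m.nk_blood_conc * m.blood_volume
    # the NK diameter is the effective thickness of the imaging plane
    nk_density_lung = m.nk_per_fov / (m.fov_area * m.nk_diameter)
    nk_total_lung = nk_density_lung * m.lung_volume
    nk_influx = m.cardiac_output * m.nk_blood_conc
    nk_decay_const = nk_influx / nk_total_lung
    nk_half_life = half_life_from_rate(nk_decay_const)
    nk_flow_rate_capillary = m.nk_blood_conc * capillary_flow_rate
    nk_linear_density = nk_total_lung / m.total_capillary_length
    crawl_hit_rate = nk_linear_density * m.nk_crawl_speed
    melanoma_decay_obs = m.kill_probability * m.observed_hit_rate
    melanoma_decay_crawl = m.kill_probability * crawl_hit_rate
    return DerivedParams(
        capillary_flow_rate=capillary_flow_rate,
        nk_whole_blood=nk_whole_blood,
        nk_density_lung=nk_density_lung,
        nk_total_lung=nk_total_lung,
        nk_influx=nk_influx,
        nk_decay_const=nk_decay_const,
        nk_half_life=nk_half_life,
        nk_flow_rate_capillary=nk_flow_rate_capillary,
        nk_linear_density=nk_linear_density,
        crawl_hit_rate=crawl_hit_rate,
        melanoma_decay_obs=melanoma_decay_obs,
        melanoma_half_life_obs=half_life_from_rate(melanoma_decay_obs),
        melanoma_decay_crawl=melanoma_decay_crawl,
        melanoma_half_life_crawl=half_life_from_rate(melanoma_decay_crawl),
    )


@dataclass(frozen=True)
class ConsistencyReport:
    """Cross-check of the three melanoma half-life estimates.

    ``ratio_*`` are the trajectory-derived half-lives divided by the
    bioluminescence-derived one; each passes when within ``tolerance`` of 1.
    """

    bli_half_life: float  # min
    obs_half_life: float  # min
    crawl_half_life: float  # min
    ratio_obs: float
    ratio_crawl: float
    tolerance: float
    obs_within: bool
    crawl_within: bool

    @property
    def consistent(self) -> bool:
        return self.obs_within and self.crawl_within

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["consistent"] = self.consistent
        return d


def consistency_report(
    derived: DerivedParams, bli_half_life: float, tolerance: float = 0.25
) -> ConsistencyReport:
    """Compare trajectory-predicted half-lives with the BLI-measured one.

    All three half-lives must be finite and positive; *tolerance* is the
    allowed relative deviation of each ratio from 1 (default 25%).
    """
    for name, value in [
        ("bli_half_life", bli_half_life),
        ("melanoma_half_life_obs", derived.melanoma_half_life_obs),
        ("melanoma_half_life_crawl", derived.melanoma_half_life_crawl),
    ]:
        if not (math.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be finite and positive, got {value!r}")
    ratio_obs = derived.melanoma_half_life_obs / bli_half_life
    ratio_crawl = derived.melanoma_half_life_crawl / bli_half_life
    return ConsistencyReport(
        bli_half_life=bli_half_life,
        obs_half_life=derived.melanoma_half_life_obs,
        crawl_half_life=derived.melanoma_half_life_crawl,
        ratio_obs=ratio_obs,
        ratio_crawl=ratio_crawl,
        tolerance=tolerance,
        obs_within=abs(ratio_obs - 1.0) <= tolerance,
        crawl_within=abs(ratio_crawl - 1.0) <= tolerance,
    )


# ---------------------------------------------------------------------------
# parameter-file I/O


def load_measured_params(source: str | Path | dict) -> MeasuredParams:
    """Load a flat key/value parameter file (YAML) into :class:`MeasuredParams`.

    Every key is ``<field>_<unit>`` (e.g. ``capillary_radius_um``); the bare
    field name is accepted for dimensionless quantities. Unknown keys,
    duplicate fields and missing fields raise ``ValueError`` naming the key.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"parameter file {source} is not a flat mapping")

    values: dict[str, float] = {}
    for key, value in raw.items():
        field, unit = _split_key(key)
        if field in values:
            raise ValueError(f"duplicate parameter for field {field!r} (key {key!r})")
        values[field] = convert(float(value), unit, _FIELD_KINDS[field])
    missing = sorted(set(_FIELD_KINDS) - set(values))
    if missing:
        raise ValueError(f"missing parameters: {missing}")
    return MeasuredParams(**values)


def _split_key(key: str) -> tuple[str, str]:
    for field, kind in _FIELD_KINDS.items():
        if key == field and "" in {u for u in allowed_units(kind)}:
            return field, ""
        if key.startswith(field + "_"):
            unit = key[len(field) + 1 :]
            if unit in allowed_units(kind):
                return field, unit
            raise ValueError(
                f"key {key!r}: unit suffix {unit!r} not valid for "
                f"{field} ({kind}); allowed: {allowed_units(kind)}"
            )
    raise ValueError(f"unknown parameter key {key!r}")


def table1_params() -> MeasuredParams:
    """The packaged default measured-parameter set."""
    ref = resources.files("nkpatrol").joinpath("data/measured_params.yaml")
    with resources.as_file(ref) as path:
        return load_measured_params(path)


# ---------------------------------------------------------------------------
# report rendering

_REPORT_ROWS = [
    # (symbol, description, field, display units, display scale, formula)
    ("Bv", "Blood volume", "blood_volume", "m^3", 1.0, "measured"),
    ("Lv", "Lung volume", "lung_volume", "m^3", 1.0, "measured"),
    ("CO", "Cardiac output", "cardiac_output", "m^3/min", 1.0, "measured"),
    ("Cp_l", "Total lung capillary length", "total_capillary_length", "m", 1.0, "measured"),
    ("FOV", "Field of view", "fov_area", "m^2", 1.0, "measured"),
    ("Plt_speed", "Platelet speed", "platelet_speed", "m/min", 1.0, "measured"),
    ("Cp_r", "Capillary radius", "capillary_radius", "m", 1.0, "measured"),
    ("NK_d", "NK cell diameter", "nk_diameter", "m", 1.0, "measured"),
    ("NK_bl", "NK cell count in blood", "nk_blood_conc", "cells/m^3", 1.0, "measured"),
    ("NK_FOV", "NK cell number in a field of view", "nk_per_fov", "cells", 1.0, "measured"),
    ("NK_speed", "NK crawling speed on capillaries", "nk_crawl_speed", "m/min", 1.0, "measured"),
    ("NK_hit_obs", "Observed NK cell hit rate", "observed_hit_rate", "hits/min", 1.0, "measured"),
    ("NK_kill", "NK cell killing probability", "kill_probability", "", 1.0, "measured"),
    ("Cp_fr", "Capillary flow rate", "capillary_flow_rate", "m^3/min", 1.0,
     "Plt_speed*pi*Cp_r^2"),
    ("NK_wbl", "Whole blood NK cells", "nk_whole_blood", "cells", 1.0, "NK_bl*Bv"),
    ("NK_density", "NK cell density in lung", "nk_density_lung", "cells/m^3", 1.0,
     "NK_FOV/(FOV*NK_d)"),
    ("NK_lung", "Total NK cells in lung", "nk_total_lung", "cells", 1.0,
     "NK_density*Lv"),
    ("NK_in", "NK cell influx to lung", "nk_influx", "cells/min", 1.0, "CO*NK_bl"),
    ("NK_out", "NK cell decay constant", "nk_decay_const", "/min", 1.0, "NK_in/NK_lung"),
    ("NK_hl", "NK cell half-life in the lung", "nk_half_life", "min", 1.0, "ln2/NK_out"),
    ("NK_fr", "NK cell flow rate per capillary", "nk_flow_rate_capillary", "cells/min",
     1.0, "NK_bl*Cp_fr"),
    ("NK_dcp", "NK cell density on capillary", "nk_linear_density", "cells/m", 1.0,
     "NK_lung/Cp_l"),
    ("NK_hit_cr", "Crawling NK cell hit rate", "crawl_hit_rate", "hits/min", 1.0,
     "NK_dcp*NK_speed"),
    ("Ml_t_2P_obs", "Melanoma decay constant (observed hit rate)",
     "melanoma_decay_obs", "/min", 1.0, "NK_kill*NK_hit_obs"),
    ("Ml_hl_2P_obs", "Melanoma half-life (observed hit rate)",
     "melanoma_half_life_obs", "min", 1.0, "ln2/Ml_t_2P_obs"),
    ("Ml_t_2P_crsp", "Melanoma decay constant (crawling speed)",
     "melanoma_decay_crawl", "/min", 1.0, "NK_kill*NK_hit_cr"),
    ("Ml_hl_2P_crsp", "Melanoma half-life (crawling speed)",
     "melanoma_half_life_crawl", "min", 1.0, "ln2/NK_kill/NK_hit_cr"),
]


def render_report(measured: MeasuredParams, derived: DerivedParams) -> str:
    """Tab-separated cascade report (symbol, description, value, units, formula).

    Values are rendered to three significant figures; the underlying cascade
    carries full precision. The capillary flow rate is the formula value
    Plt_speed*pi*Cp_r^2 (some published renderings of this quantity are
    inconsistent with their own downstream per-capillary NK flow rate).
    """
    pools = {**dataclasses.asdict(measured), **derived.as_dict()}
    lines = ["symbol\tdescription\tvalue\tunits\tformula"]
    for symbol, desc, field, unit, scale, formula in _REPORT_ROWS:
        value = pools[field] * scale
        rendered = "inf" if math.isinf(value) else f"{value:.3g}"
        lines.append(f"{symbol}\t{desc}\t{rendered}\t{unit}\t{formula}")
    return "\n".join(lines) + "\n"
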