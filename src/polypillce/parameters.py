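"""Model inputs: domain types, YAML loading/saving, and validation.

The complete input bundle for one cost-utility comparison is a
:class:`ParameterSet`: the cohort baseline profile, the two treatment arms
(intervention and comparator), event-management costs, health-state
utilities, the epidemiological assumptions used to split and kill composite
events, run settings, and the risk-equation specifications.

All proportions are stored as fractions (0.579, not 57.9%); all monetary
values are 2020 euros; cholesterol fractions are mg/dL, blood pressure is
mm Hg, hsCRP is mg/L, eGFR is mL/min/1.73m^2.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import SchemaError, ValidationError
from .risk_models import LifeTable, RiskModelSpec, load_coefficients
from . import data as _data_pkg

import importlib.resources as _resources

__all__ = [
    "CohortProfile",
    "TreatmentEffect",
    "CostSet",
    "UtilitySet",
    "EpidemiologyParams",
    "ModelSettings",
    "ParameterSet",
    "load_parameters",
    "save_parameters",
    "effective_risk_factors",
    "set_param",
    "get_param",
    "packaged_basecase_path",
]

_EPS = 1e-9


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class CohortProfile:
    """Mean baseline characteristics of the modelled cohort.

    Binary risk factors are carried as prevalence fractions and enter risk
    equations as expected-value indicators (this is a cohort model, not a
    microsimulation). ``post_chd_weight``/``post_stroke_weight`` give the
    initial split between the post-CHD and post-stroke stable states.
    """

    starting_age: float
    male_frac: float
    smoker_frac: float
    diabetes_frac: float
    afib_frac: float
    lvh_frac: float
    sbp: float
    tc: float
    hdl: float
    hscrp: float
    egfr: float
    aaa_history_frac: float
    pad_history_frac: float
    years_since_first_event: float
    post_chd_weight: float
    post_stroke_weight: float
    cohort_size: int = 1000

    _FRACTIONS = (
        "male_frac", "smoker_frac", "diabetes_frac", "afib_frac", "lvh_frac",
        "aaa_history_frac", "pad_history_frac", "post_chd_weight",
        "post_stroke_weight",
    )

    def validate(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0,1], got {v}")
        _check(abs(self.post_chd_weight + self.post_stroke_weight - 1.0) < 1e-9,
               "post_chd_weight + post_stroke_weight must equal 1")
        _check(self.starting_age > 0, "starting_age must be > 0")
        for name in ("sbp", "tc", "hdl", "egfr"):
            _check(getattr(self, name) > 0, f"{name} must be > 0")
        _check(self.years_since_first_event >= 0,
               "years_since_first_event must be >= 0")
        _check(self.cohort_size >= 1, "cohort_size must be >= 1")


@dataclass
class TreatmentEffect:
    """Arm-specific risk-factor modification and annual drug cost.

    Deltas are reductions applied to the baseline profile (HDL is an
    increment); the comparator arm of the base case carries zero deltas,
    i.e. it sits at the baseline risk-factor values.
    """

    arm_name: str
    sbp_delta: float = 0.0
    tc_delta: float = 0.0
    hdl_delta: float = 0.0
    annual_drug_cost: float = 0.0

    def validate(self) -> None:
        _check(self.annual_drug_cost >= 0, "annual_drug_cost must be >= 0")


@dataclass
class CostSet:
    """Acute-event and annual follow-up management costs (EUR, payer view)."""

    acute_chd_nonfatal: float
    acute_chd_fatal: float
    acute_stroke_nonfatal: float
    acute_stroke_fatal: float
    annual_post_chd: float
    annual_post_stroke: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")


@dataclass
class UtilitySet:
    """Health-state utilities in [0,1]; death is anchored at 0.

    The acute utility of each event type applies for exactly one cycle; a
    patient with both CHD and stroke history takes the lower of the two
    chronic utilities.
    """

    chronic_chd: float
    chronic_stroke: float
    acute_chd: float
    acute_stroke: float
    death: float = 0.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            _check(0.0 <= v <= 1.0, f"{f.name} must lie in [0,1], got {v}")
        _check(self.death == 0.0, "death utility must be 0")
        _check(self.acute_chd <= self.chronic_chd + _EPS,
               "acute_chd utility must not exceed chronic_chd")
        _check(self.acute_stroke <= self.chronic_stroke + _EPS,
               "acute_stroke utility must not exceed chronic_stroke")


@dataclass
class EpidemiologyParams:
    """Assumptions that turn a composite event risk into typed, fatal or
    nonfatal transitions, plus background mortality.

    ``chd_share_of_events`` splits the composite into CHD vs stroke;
    the case-fatality fractions split each type into fatal vs nonfatal;
    ``rr_recurrent_stroke`` scales a primary-stroke equation up to the
    recurrent setting (Framingham route only). ``life_table`` supplies
    non-cardiovascular mortality.
    """

    chd_share_of_events: float
    case_fatality_chd: float
    case_fatality_stroke: float
    rr_recurrent_stroke: float
    life_table: LifeTable
    life_table_source: str = "synthetic"

    def validate(self) -> None:
        for name in ("chd_share_of_events", "case_fatality_chd",
                     "case_fatality_stroke"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0,1], got {v}")
        _check(self.rr_recurrent_stroke > 0, "rr_recurrent_stroke must be > 0")
        self.life_table.validate()


@dataclass
class ModelSettings:
    """Run settings: horizon, cycle structure, discounting, threshold."""

    horizon_years: int
    discount_rate: float
    wtp_threshold: float
    risk_model_name: str
    first_year_cycle_len: float = 0.25
    later_cycle_len: float = 1.0
    half_cycle_correction: bool = True

    def validate(self) -> None:
        _check(self.horizon_years >= 1, "horizon_years must be >= 1")
        _check(self.discount_rate >= 0, "discount_rate must be >= 0")
        _check(self.first_year_cycle_len > 0, "first_year_cycle_len must be > 0")
        n = 1.0 / self.first_year_cycle_len
        _check(abs(n - round(n)) < 1e-9,
               "first_year_cycle_len must divide 1.0")
        _check(self.later_cycle_len > 0, "later_cycle_len must be > 0")


@dataclass
class ParameterSet:
    """The full, validated input bundle for one pairwise comparison."""

    profile: CohortProfile
    intervention: TreatmentEffect
    comparator: TreatmentEffect
    costs: CostSet
    utilities: UtilitySet
    epi: EpidemiologyParams
    settings: ModelSettings
    risk_models: dict[str, RiskModelSpec] = field(default_factory=dict)

    @property
    def arms(self) -> tuple[TreatmentEffect, TreatmentEffect]:
        """Ordered (intervention, comparator) pair."""
        return (self.intervention, self.comparator)

    def validate(self) -> None:
        self.profile.validate()
        self.intervention.validate()
        self.comparator.validate()
        self.costs.validate()
        self.utilities.validate()
        self.epi.validate()
        self.settings.validate()
        name = self.settings.risk_model_name
        if name == "framingham":
            for part in ("framingham_chd", "framingham_stroke"):
                _check(part in self.risk_models,
                       f"risk model '{part}' required by the framingham "
                       "route but absent from risk_models")
        else:
            _check(name in self.risk_models,
                   f"risk_model_name '{name}' not present in risk_models")
        for spec in self.risk_models.values():
            spec.validate()

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def effective_risk_factors(profile: CohortProfile,
                           effect: TreatmentEffect) -> CohortProfile:
    """Apply an arm's risk-factor modification to a baseline profile.

    SBP and TC are reduced by their deltas, HDL is incremented; every other
    field is unchanged. Results are floored at zero. Applying a zero-delta
    effect returns an identical profile.
    """
    return dataclasses.replace(
        profile,
        sbp=max(profile.sbp - effect.sbp_delta, 0.0),
        tc=max(profile.tc - effect.tc_delta, 0.0),
        hdl=max(profile.hdl + effect.hdl_delta, 0.0),
    )


# ---------------------------------------------------------------------------
# YAML schema
# ---------------------------------------------------------------------------

_SECTIONS = ("population", "arms", "costs", "utilities", "epidemiology",
             "settings", "risk_models")


def _require_keys(mapping: Mapping[str, Any], allowed: tuple[str, ...],
                  required: tuple[str, ...], where: str) -> None:
    for key in required:
        if key not in mapping:
            raise SchemaError(f"missing required key '{key}' in {where}")
    for key in mapping:
        if key not in allowed:
            raise SchemaError(f"unknown key '{key}' in {where}")


def _field_names(cls) -> tuple[str, ...]:
    return tuple(f.name for f in dataclasses.fields(cls))


def _build(cls, mapping: Mapping[str, Any], where: str,
           optional: tuple[str, ...] = ()):
    names = _field_names(cls)
    required = tuple(n for n in names if n not in optional)
    _require_keys(mapping, names, required, where)
    return cls(**mapping)


def packaged_basecase_path() -> Path:
    """Path of the shipped base-case parameter file."""
    return Path(_resources.files(_data_pkg) / "basecase_portugal.yaml")


def _resolve_data_path(name: str, base_dir: Path) -> Path:
    """Resolve a data-file reference: relative to the config file first,
    then to the packaged data directory."""
    p = Path(name)
    if p.is_absolute():
        return p
    local = base_dir / p
    if local.exists():
        return local
    packaged = Path(_resources.files(_data_pkg) / name)
    if packaged.exists():
        return packaged
    raise SchemaError(f"cannot resolve data file '{name}'")


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML parameter file.

    The file has sections ``population``, ``arms`` (with ``intervention``
    and ``comparator``), ``costs``, ``utilities``, ``epidemiology``,
    ``settings`` and ``risk_models``. Unknown keys are rejected; every
    invariant documented on the domain types is checked.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"parameter file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("parameter file must be a mapping at top level")
    _require_keys(raw, _SECTIONS, _SECTIONS, str(path))

    profile = _build(CohortProfile, raw["population"], "population",
                     optional=("cohort_size",))
    arms_raw = raw["arms"]
    _require_keys(arms_raw, ("intervention", "comparator"),
                  ("intervention", "comparator"), "arms")
    intervention = _build(TreatmentEffect, arms_raw["intervention"],
                          "arms.intervention",
                          optional=("sbp_delta", "tc_delta", "hdl_delta",
                                    "annual_drug_cost"))
    comparator = _build(TreatmentEffect, arms_raw["comparator"],
                        "arms.comparator",
                        optional=("sbp_delta", "tc_delta", "hdl_delta",
                                  "annual_drug_cost"))
    costs = _build(CostSet, raw["costs"], "costs")
    utilities = _build(UtilitySet, raw["utilities"], "utilities",
                       optional=("death",))

    epi_raw = dict(raw["epidemiology"])
    _require_keys(epi_raw,
                  ("chd_share_of_events", "case_fatality_chd",
                   "case_fatality_stroke", "rr_recurrent_stroke",
                   "life_table"),
                  ("chd_share_of_events", "case_fatality_chd",
                   "case_fatality_stroke", "rr_recurrent_stroke",
                   "life_table"),
                  "epidemiology")
    lt_ref = epi_raw.pop("life_table")
    if lt_ref == "synthetic":
        from .synthetic_data import generate_life_table
        life_table = generate_life_table()
    else:
        life_table = LifeTable.from_csv(_resolve_data_path(lt_ref, path.parent))
    epi = EpidemiologyParams(life_table=life_table, life_table_source=lt_ref,
                             **epi_raw)

    settings = _build(ModelSettings, raw["settings"], "settings",
                      optional=("first_year_cycle_len", "later_cycle_len",
                                "half_cycle_correction"))

    specs: dict[str, RiskModelSpec] = {}
    for name, entry in raw["risk_models"].items():
        _require_keys(entry, ("file", "baseline_survival", "horizon_years"),
                      ("file", "baseline_survival", "horizon_years"),
                      f"risk_models.{name}")
        coeff_path = _resolve_data_path(entry["file"], path.parent)
        specs[name] = RiskModelSpec(
            name=name,
            coefficients=load_coefficients(coeff_path),
            baseline_survival=float(entry["baseline_survival"]),
            horizon_years=float(entry["horizon_years"]),
            source_file=entry["file"],
        )

    params = ParameterSet(profile=profile, intervention=intervention,
                          comparator=comparator, costs=costs,
                          utilities=utilities, epi=epi, settings=settings,
                          risk_models=specs)
    params.validate()
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet back to the YAML schema read by
    :func:`load_parameters` (round-trips bit-exactly)."""
    def as_dict(obj, skip=()):
        return {f.name: getattr(obj, f.name)
                for f in dataclasses.fields(obj) if f.name not in skip}

    doc = {
        "population": as_dict(params.profile),
        "arms": {
            "intervention": as_dict(params.intervention),
            "comparator": as_dict(params.comparator),
        },
        "costs": as_dict(params.costs),
        "utilities": as_dict(params.utilities),
        "epidemiology": {
            "chd_share_of_events": params.epi.chd_share_of_events,
            "case_fatality_chd": params.epi.case_fatality_chd,
            "case_fatality_stroke": params.epi.case_fatality_stroke,
            "rr_recurrent_stroke": params.epi.rr_recurrent_stroke,
            "life_table": params.epi.life_table_source,
        },
        "settings": as_dict(params.settings),
        "risk_models": {
            name: {"file": spec.source_file,
                   "baseline_survival": spec.baseline_survival,
                   "horizon_years": spec.horizon_years}
            for name, spec in params.risk_models.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Parameter paths (used by OWSA and scenario overrides)
# ---------------------------------------------------------------------------

_PATH_ROOTS = {
    "population": "profile",
    "arms.intervention": "intervention",
    "arms.comparator": "comparator",
    "costs": "costs",
    "utilities": "utilities",
    "epidemiology": "epi",
    "settings": "settings",
}


def _resolve_root(path: str) -> tuple[str, str]:
    for prefix, attr in _PATH_ROOTS.items():
        if path.startswith(prefix + "."):
            return attr, path[len(prefix) + 1:]
    raise KeyError(path)


def get_param(params: ParameterSet, path: str) -> Any:
    """Read a scalar by dotted path, e.g. ``costs.annual_post_chd`` or
    ``risk_models.smart.baseline_survival``."""
    if path.startswith("risk_models."):
        _, model, fieldname = path.split(".", 2)
        return getattr(params.risk_models[model], fieldname)
    attr, leaf = _resolve_root(path)
    obj = getattr(params, attr)
    if not hasattr(obj, leaf):
        raise KeyError(path)
    return getattr(obj, leaf)


def set_param(params: ParameterSet, path: str, value: Any,
              validate: bool = False) -> ParameterSet:
    """Return a copy of ``params`` with one scalar replaced.

    Overriding ``population.post_chd_weight`` keeps the initial occupancy
    stochastic by setting the stroke weight to its complement. With
    ``validate=False`` (the default, used by sensitivity sweeps) invariants
    are deliberately not re-checked so that mechanical ±20% excursions
    outside natural bounds are representable.
    """
    new = params.copy()
    if path.startswith("risk_models."):
        _, model, fieldname = path.split(".", 2)
        if model not in new.risk_models:
            raise KeyError(path)
        setattr(new.risk_models[model], fieldname, value)
    else:
        attr, leaf = _resolve_root(path)
        obj = getattr(new, attr)
        if not hasattr(obj, leaf):
            raise KeyError(path)
        setattr(obj, leaf, value)
        if path == "population.post_chd_weight":
            new.profile.post_stroke_weight = 1.0 - value
        elif path == "population.post_stroke_weight":
            new.profile.post_chd_weight = 1.0 - value
    if validate:
        new.validate()
    return new
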