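"""Typed model inputs, validation, parameter registry and config file I/O.

Every scalar input of the economic model (unit costs, utilities, adverse-event
risks, body weight, discount rate, ...) is carried together with its
uncertainty description -- a distribution family plus (base, min, max) -- so
that the deterministic engine, the one-way sensitivity sweep and the
probabilistic sensitivity analysis all address the same quantities through a
single registry of stable string ids (``cost.drug.tdxd``, ``util.pfs``, ...).

The base case shipped with the package (``data/destiny_b04.yaml``) encodes the
published model of trastuzumab deruxtecan (T-DXd) versus physician's-choice
chemotherapy for HER2-low advanced breast cancer: Weibull overall-survival and
progression-free-survival parameters per arm for the overall, hormone-
receptor-positive and hormone-receptor-negative cohorts, 2022 USD unit costs,
health-state utilities and grade-3/4 adverse-event disutilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "WeibullParams",
    "DistributionSpec",
    "StrategyInputs",
    "SharedInputs",
    "CohortSpec",
    "ModelConfig",
    "load_model_config",
    "load_base_case",
    "write_config",
    "scale_cost_by_weight",
    "parameter_registry",
    "perturb",
    "ParameterRef",
    "BASE_CASE_RESOURCE",
]

BASE_CASE_RESOURCE = "destiny_b04.yaml"

_FAMILIES = ("beta", "gamma", "normal", "uniform")


class ConfigError(ValueError):
    """Aggregated validation failure; ``errors`` lists every offending field."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid model configuration:\n  " + "\n  ".join(self.errors))


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival parameters on the hazard scale: S(t) = exp(-scale * t**shape)."""

    scale: float
    shape: float

    def __post_init__(self):
        if not (self.scale > 0 and self.shape > 0):
            raise ValueError(
                f"Weibull scale and shape must be positive, got ({self.scale}, {self.shape})"
            )


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty description of one scalar: family plus (mean, low, high).

    ``low``/``high`` are the deterministic sensitivity range; the probabilistic
    samplers are moment-matched to ``mean`` and sd = (high - low) / 3.92.
    """

    family: str
    mean: float
    low: float
    high: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not (self.low <= self.mean <= self.high):
            raise ValueError(
                f"require low <= mean <= high, got ({self.low}, {self.mean}, {self.high})"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError("beta family requires support within [0, 1]")
        if self.family == "gamma" and self.low < 0:
            raise ValueError("gamma family requires non-negative support")


@dataclass(frozen=True)
class StrategyInputs:
    """Economic description of one treatment arm.

    ``treatment_duration_factor`` scales the number of effective drug +
    administration cycles relative to time spent progression free; see
    docs/methods.md for the calibration that fixes it per arm and cohort.
    """

    name: str
    os: WeibullParams
    pfs: WeibullParams
    drug_cost_per_cycle: float
    ae_cost_total: float
    ae_risks: Mapping[str, float]
    bsc_rate: float
    weight_scaled: bool = False
    treatment_duration_factor: float = 1.0

    def validation_errors(self) -> list[str]:
        errs = []
        pre = f"strategy {self.name!r}: "
        for fname in ("drug_cost_per_cycle", "ae_cost_total"):
            if getattr(self, fname) < 0:
                errs.append(pre + f"{fname} must be >= 0")
        for ae, risk in self.ae_risks.items():
            if not 0.0 <= risk <= 1.0:
                errs.append(pre + f"ae_risks[{ae!r}] = {risk} outside [0, 1]")
        if not 0.0 <= self.bsc_rate <= 1.0:
            errs.append(pre + f"bsc_rate = {self.bsc_rate} outside [0, 1]")
        if not 0.0 < self.treatment_duration_factor <= 1.0:
            errs.append(pre + "treatment_duration_factor must lie in (0, 1]")
        return errs


@dataclass(frozen=True)
class SharedInputs:
    """Inputs common to both arms: unit costs, utilities, timing and engine knobs.

    Engine knobs (all default to the calibrated base case):

    - ``fitted_unit_weeks``: length of one unit of the fitted Weibull time
      scale; 6 weeks (= one cycle) reproduces the published life-years.
    - ``discount_lys``: life-years are reported undiscounted in the base case
      (costs and QALYs are always discounted at ``annual_discount``).
    - ``half_cycle``: midpoint occupancy weighting instead of cycle-start.
    - ``followup_in_pfs_only``: restrict the follow-up cost line to the
      progression-free state instead of all alive states.
    """

    admin_cost_per_cycle: float
    followup_cost_per_cycle: float
    bsc_cost_per_cycle: float
    ihc_cost: float
    terminal_cost: float
    utility_pfs: float
    utility_pd: float
    disutilities: Mapping[str, float]
    weight: float
    base_weight: float
    bsa: float
    annual_discount: float
    cycle_length_weeks: float = 6.0
    fitted_unit_weeks: float = 6.0
    horizon_years: float = 15.0
    wtp: float = 150_000.0
    discount_lys: bool = False
    half_cycle: bool = False
    followup_in_pfs_only: bool = False

    def validation_errors(self) -> list[str]:
        errs = []
        if not 0.0 <= self.utility_pd <= self.utility_pfs <= 1.0:
            errs.append(
                f"require 0 <= utility_pd <= utility_pfs <= 1, got "
                f"({self.utility_pd}, {self.utility_pfs})"
            )
        for fname in (
            "admin_cost_per_cycle",
            "followup_cost_per_cycle",
            "bsc_cost_per_cycle",
            "ihc_cost",
            "terminal_cost",
        ):
            if getattr(self, fname) < 0:
                errs.append(f"{fname} must be >= 0")
        for ae, du in self.disutilities.items():
            if not 0.0 <= du <= 1.0:
                errs.append(f"disutilities[{ae!r}] = {du} outside [0, 1]")
        if not 0.0 <= self.annual_discount <= 1.0:
            errs.append(f"annual_discount = {self.annual_discount} outside [0, 1]")
        if self.weight <= 0 or self.base_weight <= 0:
            errs.append("weight and base_weight must be positive")
        if self.horizon_years <= 0:
            errs.append("horizon_years must be positive")
        if self.cycle_length_weeks <= 0 or self.fitted_unit_weeks <= 0:
            errs.append("cycle_length_weeks and fitted_unit_weeks must be positive")
        if self.wtp < 0:
            errs.append("wtp must be >= 0")
        return errs


@dataclass(frozen=True)
class CohortSpec:
    """One cohort's full comparison: reference (chemo) arm, comparator (T-DXd) arm, shared inputs."""

    label: str
    chemo: StrategyInputs
    tdxd: StrategyInputs
    shared: SharedInputs

    def validate(self) -> "CohortSpec":
        errs = (
            self.chemo.validation_errors()
            + self.tdxd.validation_errors()
            + self.shared.validation_errors()
        )
        for arm in (self.chemo, self.tdxd):
            missing = set(arm.ae_risks) - set(self.shared.disutilities)
            if missing:
                errs.append(
                    f"strategy {arm.name!r}: adverse events {sorted(missing)} have no disutility"
                )
        if errs:
            raise ConfigError(errs)
        return self


@dataclass(frozen=True)
class ModelConfig:
    """Parsed model configuration: one CohortSpec per cohort plus the PSA/OWSA distributions.

    ``distributions`` maps registry parameter ids to their DistributionSpec;
    Table-1 scalars are shared across cohorts, so one map serves all cohorts.
    """

    cohorts: Mapping[str, CohortSpec]
    distributions: Mapping[str, DistributionSpec]
    name: str = "model"

    def cohort(self, label: str) -> CohortSpec:
        try:
            return self.cohorts[label]
        except KeyError:
            raise KeyError(
                f"unknown cohort {label!r}; available: {sorted(self.cohorts)}"
            ) from None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def scale_cost_by_weight(base_cost: float, base_weight: float, weight: float) -> float:
    """Linear body-weight scaling of a per-cycle drug cost (mg/kg dosing)."""
    if base_weight <= 0 or weight <= 0:
        raise ValueError("weights must be positive")
    return base_cost * (weight / base_weight)


@dataclass(frozen=True)
class ParameterRef:
    """Registry entry: a stable id with getter/setter closures over a CohortSpec."""

    pid: str
    get: Callable[[CohortSpec], float]
    set: Callable[[CohortSpec, float], CohortSpec]


def _shared_ref(pid: str, fname: str) -> ParameterRef:
    return ParameterRef(
        pid,
        lambda s: getattr(s.shared, fname),
        lambda s, v: replace(s, shared=replace(s.shared, **{fname: v})),
    )


def _arm_ref(pid: str, arm: str, fname: str) -> ParameterRef:
    return ParameterRef(
        pid,
        lambda s: getattr(getattr(s, arm), fname),
        lambda s, v: replace(s, **{arm: replace(getattr(s, arm), **{fname: v})}),
    )


def _map_ref(pid: str, getter, setter) -> ParameterRef:
    return ParameterRef(pid, getter, setter)


def parameter_registry(spec: CohortSpec) -> dict[str, ParameterRef]:
    """Enumerate every registered scalar of a cohort comparison.

    Ids are stable strings: ``cost.drug.<arm>``, ``cost.ae.<arm>``,
    ``bsc_rate.<arm>``, ``risk.<arm>.<ae>``, ``cost.admin``, ``cost.followup``,
    ``cost.bsc``, ``cost.ihc``, ``cost.terminal``, ``util.pfs``, ``util.pd``,
    ``disutil.<ae>``, ``weight``, ``bsa``, ``discount``.
    """
    refs: list[ParameterRef] = [
        _shared_ref("cost.admin", "admin_cost_per_cycle"),
        _shared_ref("cost.followup", "followup_cost_per_cycle"),
        _shared_ref("cost.bsc", "bsc_cost_per_cycle"),
        _shared_ref("cost.ihc", "ihc_cost"),
        _shared_ref("cost.terminal", "terminal_cost"),
        _shared_ref("util.pfs", "utility_pfs"),
        _shared_ref("util.pd", "utility_pd"),
        _shared_ref("weight", "weight"),
        _shared_ref("bsa", "bsa"),
        _shared_ref("discount", "annual_discount"),
    ]
    for ae in spec.shared.disutilities:
        def _get(s, ae=ae):
            return s.shared.disutilities[ae]

        def _set(s, v, ae=ae):
            du = dict(s.shared.disutilities)
            du[ae] = v
            return replace(s, shared=replace(s.shared, disutilities=du))

        refs.append(_map_ref(f"disutil.{ae}", _get, _set))
    for arm in ("chemo", "tdxd"):
        refs.append(_arm_ref(f"cost.drug.{arm}", arm, "drug_cost_per_cycle"))
        refs.append(_arm_ref(f"cost.ae.{arm}", arm, "ae_cost_total"))
        refs.append(_arm_ref(f"bsc_rate.{arm}", arm, "bsc_rate"))
        for ae in getattr(spec, arm).ae_risks:
            def _get(s, arm=arm, ae=ae):
                return getattr(s, arm).ae_risks[ae]

            def _set(s, v, arm=arm, ae=ae):
                a = getattr(s, arm)
                risks = dict(a.ae_risks)
                risks[ae] = v
                return replace(s, **{arm: replace(a, ae_risks=risks)})

            refs.append(_map_ref(f"risk.{arm}.{ae}", _get, _set))
    return {r.pid: r for r in refs}


def perturb(spec: CohortSpec, pid: str, value: float) -> CohortSpec:
    """Return a copy of ``spec`` with exactly the scalar ``pid`` replaced by ``value``."""
    registry = parameter_registry(spec)
    if pid not in registry:
        raise KeyError(f"unknown parameter id {pid!r}; known ids: {sorted(registry)}")
    return registry[pid].set(spec, value)


# ---------------------------------------------------------------------------
# config file I/O
# ---------------------------------------------------------------------------


def _get(section: Mapping, key: str, errs: list[str], where: str):
    if key not in section:
        errs.append(f"missing field {where}.{key}")
        return None
    return section[key]


def _scalar(section: Mapping, key: str, errs: list[str], where: str):
    """Read a plain numeric field."""
    v = _get(section, key, errs, where)
    if v is None:
        return 0.0
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        errs.append(f"{where}.{key} must be a number, got {v!r}")
        return 0.0
    return float(v)


def _dist(section: Mapping, key: str, errs: list[str], where: str, dists: dict, pid: str):
    """Read a ``{base, low, high, family}`` entry; register its distribution under ``pid``."""
    v = _get(section, key, errs, where)
    if v is None:
        return 0.0
    if not isinstance(v, Mapping) or "base" not in v:
        errs.append(f"{where}.{key} must be a mapping with base/low/high/family")
        return 0.0
    base = float(v["base"])
    try:
        dists[pid] = DistributionSpec(
            family=str(v.get("family", "uniform")),
            mean=base,
            low=float(v.get("low", base)),
            high=float(v.get("high", base)),
        )
    except ValueError as e:
        errs.append(f"{where}.{key}: {e}")
    return base


def _weibull(section: Mapping, key: str, errs: list[str], where: str) -> WeibullParams:
    v = _get(section, key, errs, where)
    if not isinstance(v, Mapping) or "scale" not in v or "shape" not in v:
        errs.append(f"{where}.{key} must be a mapping with scale and shape")
        return WeibullParams(1.0, 1.0)
    try:
        return WeibullParams(float(v["scale"]), float(v["shape"]))
    except ValueError as e:
        errs.append(f"{where}.{key}: {e}")
        return WeibullParams(1.0, 1.0)


def _parse(doc: Mapping) -> ModelConfig:
    errs: list[str] = []
    dists: dict[str, DistributionSpec] = {}

    sh = doc.get("shared", {})
    weight = _dist(sh, "weight_kg", errs, "shared", dists, "weight")
    shared = SharedInputs(
        admin_cost_per_cycle=_dist(sh, "admin_cost_per_cycle", errs, "shared", dists, "cost.admin"),
        followup_cost_per_cycle=_dist(sh, "followup_cost_per_cycle", errs, "shared", dists, "cost.followup"),
        bsc_cost_per_cycle=_dist(sh, "bsc_cost_per_cycle", errs, "shared", dists, "cost.bsc"),
        ihc_cost=_dist(sh, "ihc_cost", errs, "shared", dists, "cost.ihc"),
        terminal_cost=_dist(sh, "terminal_cost", errs, "shared", dists, "cost.terminal"),
        utility_pfs=_dist(sh, "utility_pfs", errs, "shared", dists, "util.pfs"),
        utility_pd=_dist(sh, "utility_pd", errs, "shared", dists, "util.pd"),
        disutilities={
            str(ae): _dist(sh.get("disutilities", {}), ae, errs, "shared.disutilities",
                           dists, f"disutil.{ae}")
            for ae in sh.get("disutilities", {})
        },
        weight=weight,
        base_weight=weight,
        bsa=_dist(sh, "bsa_m2", errs, "shared", dists, "bsa"),
        annual_discount=_dist(sh, "annual_discount", errs, "shared", dists, "discount"),
        cycle_length_weeks=_scalar(sh, "cycle_length_weeks", errs, "shared"),
        fitted_unit_weeks=_scalar(sh, "fitted_unit_weeks", errs, "shared"),
        horizon_years=_scalar(sh, "horizon_years", errs, "shared"),
        wtp=_scalar(sh, "wtp", errs, "shared"),
        discount_lys=bool(sh.get("discount_lys", False)),
        half_cycle=bool(sh.get("half_cycle", False)),
        followup_in_pfs_only=bool(sh.get("followup_in_pfs_only", False)),
    )

    arms = doc.get("arms", {})

    def build_arm(arm: str, cohort_label: str, cohort_section: Mapping) -> StrategyInputs:
        a = arms.get(arm, {})
        c = cohort_section.get(arm, {})
        where = f"arms.{arm}"
        return StrategyInputs(
            name=arm,
            os=_weibull(c, "os", errs, f"cohorts.{cohort_label}.{arm}"),
            pfs=_weibull(c, "pfs", errs, f"cohorts.{cohort_label}.{arm}"),
            drug_cost_per_cycle=_dist(a, "drug_cost_per_cycle", errs, where, dists, f"cost.drug.{arm}"),
            ae_cost_total=_dist(a, "ae_cost_total", errs, where, dists, f"cost.ae.{arm}"),
            ae_risks={
                str(ae): _dist(a.get("ae_risks", {}), ae, errs, f"{where}.ae_risks",
                               dists, f"risk.{arm}.{ae}")
                for ae in a.get("ae_risks", {})
            },
            bsc_rate=_dist(a, "bsc_rate", errs, where, dists, f"bsc_rate.{arm}"),
            weight_scaled=bool(a.get("weight_scaled", False)),
            treatment_duration_factor=float(
                c.get("treatment_duration_factor", a.get("treatment_duration_factor", 1.0))
            ),
        )

    cohorts: dict[str, CohortSpec] = {}
    for label, csec in doc.get("cohorts", {}).items():
        spec = CohortSpec(
            label=str(label),
            chemo=build_arm("chemo", label, csec),
            tdxd=build_arm("tdxd", label, csec),
            shared=shared,
        )
        sub_errs = (
            spec.chemo.validation_errors()
            + spec.tdxd.validation_errors()
            + spec.shared.validation_errors()
        )
        errs.extend(f"cohorts.{label}: {e}" for e in sub_errs)
        cohorts[str(label)] = spec
    if not cohorts:
        errs.append("no cohorts defined")
    if errs:
        raise ConfigError(sorted(set(errs)))
    for spec in cohorts.values():
        spec.validate()
    return ModelConfig(
        cohorts=cohorts, distributions=dists, name=str(doc.get("name", "model"))
    )


def load_model_config(path) -> ModelConfig:
    """Load and validate a declarative model config (YAML dialect, see packaged base case).

    All validation problems are aggregated into a single :class:`ConfigError`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError(["config root must be a mapping"])
    return _parse(doc)


def load_base_case() -> ModelConfig:
    """The packaged base case: the published T-DXd vs chemotherapy model inputs."""
    ref = resources.files("her2low_cea").joinpath("data", BASE_CASE_RESOURCE)
    with resources.as_file(ref) as path:
        return load_model_config(path)


def _dist_entry(d: DistributionSpec) -> dict:
    return {"base": d.mean, "low": d.low, "high": d.high, "family": d.family}


def write_config(config: ModelConfig, path) -> None:
    """Serialize a ModelConfig back to the YAML dialect (round-trips with load)."""
    any_cohort = next(iter(config.cohorts.values()))
    sh = any_cohort.shared
    d = config.distributions

    def entry(pid, base):
        spec = d.get(pid)
        if spec is None:
            spec = DistributionSpec("uniform", base, base, base)
        return _dist_entry(replace(spec, mean=base))

    doc = {
        "name": config.name,
        "shared": {
            "admin_cost_per_cycle": entry("cost.admin", sh.admin_cost_per_cycle),
            "followup_cost_per_cycle": entry("cost.followup", sh.followup_cost_per_cycle),
            "bsc_cost_per_cycle": entry("cost.bsc", sh.bsc_cost_per_cycle),
            "ihc_cost": entry("cost.ihc", sh.ihc_cost),
            "terminal_cost": entry("cost.terminal", sh.terminal_cost),
            "utility_pfs": entry("util.pfs", sh.utility_pfs),
            "utility_pd": entry("util.pd", sh.utility_pd),
            "disutilities": {
                ae: entry(f"disutil.{ae}", v) for ae, v in sh.disutilities.items()
            },
            "weight_kg": entry("weight", sh.base_weight),
            "bsa_m2": entry("bsa", sh.bsa),
            "annual_discount": entry("discount", sh.annual_discount),
            "cycle_length_weeks": sh.cycle_length_weeks,
            "fitted_unit_weeks": sh.fitted_unit_weeks,
            "horizon_years": sh.horizon_years,
            "wtp": sh.wtp,
            "discount_lys": sh.discount_lys,
            "half_cycle": sh.half_cycle,
            "followup_in_pfs_only": sh.followup_in_pfs_only,
        },
        "arms": {},
        "cohorts": {},
    }
    for arm in ("chemo", "tdxd"):
        a = getattr(any_cohort, arm)
        doc["arms"][arm] = {
            "drug_cost_per_cycle": entry(f"cost.drug.{arm}", a.drug_cost_per_cycle),
            "ae_cost_total": entry(f"cost.ae.{arm}", a.ae_cost_total),
            "ae_risks": {
                ae: entry(f"risk.{arm}.{ae}", v) for ae, v in a.ae_risks.items()
            },
            "bsc_rate": entry(f"bsc_rate.{arm}", a.bsc_rate),
            "weight_scaled": a.weight_scaled,
        }
    for label, spec in config.cohorts.items():
        doc["cohorts"][label] = {
            arm: {
                "os": {"scale": getattr(spec, arm).os.scale, "shape": getattr(spec, arm).os.shape},
                "pfs": {"scale": getattr(spec, arm).pfs.scale, "shape": getattr(spec, arm).pfs.shape},
                "treatment_duration_factor": getattr(spec, arm).treatment_duration_factor,
            }
            for arm in ("chemo", "tdxd")
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
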