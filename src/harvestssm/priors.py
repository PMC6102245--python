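"""Prior distributions for the demographic parameters.

Three families are supported:

``gamma``
    shape/rate parameterization, used for litter sizes;
``beta``
    used for pregnancy rates and the newborn sex proportion;
``hierarchical-link-normal``
    survival-type probabilities whose long-term mean has a normal prior on
    the complementary log-log mortality link scale (``link(s) =
    log(-log(s))``), with a fixed long-term precision and, for
    year-varying parameters, a gamma hyperprior on the annual link-scale
    precision.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .population import (
    FECUNDITY_GROUP_LABELS,
    N_AGE_CLASSES,
    survival_from_link,
    survival_to_link,
)

__all__ = [
    "BETA",
    "GAMMA",
    "HIERARCHICAL",
    "DemographicPriors",
    "InfeasibleScenarioError",
    "InitialPopulationPrior",
    "PriorSchemaError",
    "PriorSpec",
    "build_default_priors",
    "dump_priors",
    "packaged_config_path",
    "perturb_prior",
    "prior_mean",
    "prior_sd",
    "sample_prior",
]

BETA = "beta"
GAMMA = "gamma"
HIERARCHICAL = "hierarchical-link-normal"

_FAMILIES = (BETA, GAMMA, HIERARCHICAL)


class PriorSchemaError(ValueError):
    """Raised when a prior configuration file is malformed."""


class InfeasibleScenarioError(ValueError):
    """A prior perturbation pushed a mean outside the family's support.

    Mirrors the "N/A" rows of the sensitivity report: the scenario is
    reported infeasible rather than run with a clipped prior.
    """


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of one prior distribution.

    For ``beta``/``gamma``, ``hyper_a``/``hyper_b`` are (alpha, beta) and
    (shape, rate). For ``hierarchical-link-normal``, ``real_scale_mean``
    is the probability-scale mean, ``hyper_a`` the implied link-scale
    mean, ``long_term_precision`` the fixed link-scale precision of the
    long-term mean, and ``annual_precision_prior`` the optional gamma
    (shape, rate) hyperprior on the annual link-scale precision.
    """

    name: str
    family: str
    hyper_a: float | None = None
    hyper_b: float | None = None
    real_scale_mean: float | None = None
    long_term_precision: float | None = None
    annual_precision_prior: tuple[float, float] | None = None
    link: str = "identity"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unsupported prior family: {self.family!r}")
        if self.family in (BETA, GAMMA):
            if self.hyper_a is None or self.hyper_b is None:
                raise ValueError(f"{self.name}: {self.family} prior needs two hyperparameters")
            if self.hyper_a <= 0 or self.hyper_b <= 0:
                raise ValueError(f"{self.name}: hyperparameters must be positive")
            mean = _analytic_mean(self)
            if self.real_scale_mean is None:
                object.__setattr__(self, "real_scale_mean", mean)
            if self.family == BETA and not 0.0 < mean < 1.0:
                raise ValueError(f"{self.name}: beta mean must lie in (0, 1)")
        else:
            if self.real_scale_mean is None or not 0.0 < self.real_scale_mean < 1.0:
                raise ValueError(f"{self.name}: link-normal prior needs a mean in (0, 1)")
            if self.long_term_precision is None or self.long_term_precision <= 0:
                raise ValueError(f"{self.name}: link-normal prior needs a positive precision")
            object.__setattr__(self, "link", "cloglog")
            if self.hyper_a is None:
                object.__setattr__(self, "hyper_a", survival_to_link(self.real_scale_mean))
        if self.annual_precision_prior is not None:
            shape, rate = self.annual_precision_prior
            if shape <= 0 or rate <= 0:
                raise ValueError(f"{self.name}: annual precision hyperprior must be positive")
            object.__setattr__(self, "annual_precision_prior", (float(shape), float(rate)))

    @property
    def link_mean(self) -> float:
        if self.family != HIERARCHICAL:
            raise ValueError(f"{self.name}: link mean only defined for link-normal priors")
        return float(self.hyper_a)

    @property
    def link_sd(self) -> float:
        if self.family != HIERARCHICAL:
            raise ValueError(f"{self.name}: link sd only defined for link-normal priors")
        return 1.0 / math.sqrt(float(self.long_term_precision))


def _analytic_mean(spec: PriorSpec) -> float:
    if spec.family == GAMMA:
        return float(spec.hyper_a) / float(spec.hyper_b)
    if spec.family == BETA:
        return float(spec.hyper_a) / (float(spec.hyper_a) + float(spec.hyper_b))
    if spec.family == HIERARCHICAL:
        return float(spec.real_scale_mean)
    raise ValueError(f"unsupported prior family: {spec.family!r}")


def prior_mean(spec: PriorSpec) -> float:
    """Analytic mean on the real (natural) parameter scale.

    For the hierarchical link-normal family this is the stated
    probability-scale centre (the link-scale prior is centred so that the
    inverse link of its mean equals it).
    """
    return _analytic_mean(spec)


def prior_sd(spec: PriorSpec) -> float:
    """Analytic real-scale standard deviation.

    Closed form for beta and gamma. For the hierarchical link-normal
    family a first-order (delta method) approximation is returned:
    ``|s * log(s)| * sigma_link`` evaluated at the mean.
    """
    if spec.family == GAMMA:
        return math.sqrt(float(spec.hyper_a)) / float(spec.hyper_b)
    if spec.family == BETA:
        a, b = float(spec.hyper_a), float(spec.hyper_b)
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    if spec.family == HIERARCHICAL:
        s = float(spec.real_scale_mean)
        return abs(s * math.log(s)) * spec.link_sd
    raise ValueError(f"unsupported prior family: {spec.family!r}")


def sample_prior(spec: PriorSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent samples on the real scale, deterministically."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == GAMMA:
        return rng.gamma(shape=spec.hyper_a, scale=1.0 / spec.hyper_b, size=n)
    if spec.family == BETA:
        return rng.beta(spec.hyper_a, spec.hyper_b, size=n)
    eta = rng.normal(spec.link_mean, spec.link_sd, size=n)
    return survival_from_link(eta)


def perturb_prior(spec: PriorSpec, relative_bias: float) -> PriorSpec:
    """Return a spec whose real-scale mean is ``(1 + bias)`` times the original.

    Beta priors keep their concentration ``alpha + beta`` (prior sample
    size); gamma priors keep their rate; link-normal priors shift the
    centre with precisions unchanged. A probability mean pushed outside
    (0, 1) raises :class:`InfeasibleScenarioError`.
    """
    if relative_bias <= -1.0:
        raise ValueError("relative bias must exceed -1")
    if relative_bias == 0.0:
        return spec
    new_mean = _analytic_mean(spec) * (1.0 + relative_bias)
    if spec.family == GAMMA:
        return replace(spec, hyper_a=spec.hyper_a * (1.0 + relative_bias),
                       real_scale_mean=None)
    if new_mean >= 1.0 or new_mean <= 0.0:
        raise InfeasibleScenarioError(
            f"{spec.name}: perturbed mean {new_mean:.4f} outside (0, 1)"
        )
    if spec.family == BETA:
        conc = float(spec.hyper_a) + float(spec.hyper_b)
        return replace(spec, hyper_a=new_mean * conc, hyper_b=(1.0 - new_mean) * conc,
                       real_scale_mean=None)
    return replace(spec, real_scale_mean=new_mean, hyper_a=None)


# ---------------------------------------------------------------------------
# the full prior set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialPopulationPrior:
    """Prior on the initial (year-1) abundance allocation.

    The total is lognormal around ``n_total`` with log-scale spread
    ``dispersion``; the allocation over the ``A x 2`` age/sex classes is
    fixed at ``age_sex_proportions`` (the long-run harvest proportions).
    """

    n_total: float = 21450.0
    age_sex_proportions: np.ndarray = None
    dispersion: float = 0.2

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        props = np.asarray(self.age_sex_proportions, dtype=float)
        if props.ndim != 2 or props.shape[1] != 2:
            raise ValueError("age_sex_proportions must have shape (A, 2)")
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(float(props.sum()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        object.__setattr__(self, "age_sex_proportions", props)


@dataclass(frozen=True)
class DemographicPriors:
    """The complete packaged prior set."""

    LS: tuple[PriorSpec, ...]       # 4 fecundity groups
    PR: tuple[PriorSpec, ...]       # 4 fecundity groups
    SP: PriorSpec                   # proportion of newborns that are female
    CubSa: PriorSpec
    CubSb: PriorSpec
    HSf: PriorSpec
    HSm: PriorSpec
    NS: PriorSpec
    Rep: PriorSpec
    initial_population: InitialPopulationPrior
    age_offset_sd: float = 1.0
    n_age_offsets: int = 3

    def __post_init__(self) -> None:
        if len(self.LS) != 4 or len(self.PR) != 4:
            raise ValueError("LS and PR need one spec per fecundity group")
        for spec in (self.HSf, self.HSm, self.NS, self.Rep, self.CubSa, self.CubSb):
            if spec.family != HIERARCHICAL:
                raise ValueError(f"{spec.name}: survival-type priors must be link-normal")
        for spec in (self.HSf, self.HSm, self.NS):
            if spec.annual_precision_prior is None:
                raise ValueError(f"{spec.name}: year-varying prior needs an annual precision hyperprior")

    def all_specs(self) -> dict[str, PriorSpec]:
        out = {}
        for group, spec in zip(FECUNDITY_GROUP_LABELS, self.LS):
            out[f"LS_{group}"] = spec
        for group, spec in zip(FECUNDITY_GROUP_LABELS, self.PR):
            out[f"PR_{group}"] = spec
        out.update(SP=self.SP, CubSa=self.CubSa, CubSb=self.CubSb,
                   HSf=self.HSf, HSm=self.HSm, NS=self.NS, Rep=self.Rep)
        return out


def packaged_config_path() -> Path:
    return Path(resources.files("harvestssm") / "config" / "priors.yaml")


def _require(mapping: dict, key: str, context: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise PriorSchemaError(f"missing required field {context}.{key}")
    return mapping[key]


def _parse_beta_gamma(name: str, node: dict, context: str) -> PriorSpec:
    family = _require(node, "family", context)
    try:
        if family == GAMMA:
            return PriorSpec(name=name, family=GAMMA,
                             hyper_a=float(_require(node, "shape", context)),
                             hyper_b=float(_require(node, "rate", context)))
        if family == BETA:
            return PriorSpec(name=name, family=BETA,
                             hyper_a=float(_require(node, "alpha", context)),
                             hyper_b=float(_require(node, "beta", context)))
    except (TypeError, ValueError) as exc:
        raise PriorSchemaError(f"invalid value in {context}: {exc}") from exc
    raise PriorSchemaError(f"unsupported family {family!r} at {context}.family")


def _parse_link_normal(name: str, node: dict, context: str,
                       annual_required: bool = False) -> PriorSpec:
    mean = float(_require(node, "mean", context))
    prec = float(_require(node, "long_term_precision", context))
    annual = node.get("annual_precision_prior")
    if annual_required and annual is None:
        raise PriorSchemaError(f"missing required field {context}.annual_precision_prior")
    app = None
    if annual is not None:
        app = (float(_require(annual, "shape", context + ".annual_precision_prior")),
               float(_require(annual, "rate", context + ".annual_precision_prior")))
    try:
        return PriorSpec(name=name, family=HIERARCHICAL, real_scale_mean=mean,
                         long_term_precision=prec, annual_precision_prior=app)
    except ValueError as exc:
        raise PriorSchemaError(f"invalid value in {context}: {exc}") from exc


def build_default_priors(config_path: str | Path | None = None) -> DemographicPriors:
    """Load the packaged prior set, or a user configuration with the same schema."""
    path = Path(config_path) if config_path is not None else packaged_config_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PriorSchemaError("prior config must be a mapping")

    rec = _require(raw, "recruitment", "<root>")
    ls_node = _require(rec, "litter_size", "recruitment")
    pr_node = _require(rec, "pregnancy_rate", "recruitment")
    ls = tuple(
        _parse_beta_gamma(f"LS_{g}", _require(ls_node, g, "recruitment.litter_size"),
                          f"recruitment.litter_size.{g}")
        for g in FECUNDITY_GROUP_LABELS
    )
    pr = tuple(
        _parse_beta_gamma(f"PR_{g}", _require(pr_node, g, "recruitment.pregnancy_rate"),
                          f"recruitment.pregnancy_rate.{g}")
        for g in FECUNDITY_GROUP_LABELS
    )
    sp = _parse_beta_gamma("SP", _require(rec, "sex_proportion_female", "recruitment"),
                           "recruitment.sex_proportion_female")

    surv = _require(raw, "survival", "<root>")
    hs = _require(surv, "harvest_season", "survival")
    hsf = _parse_link_normal("HSf", _require(hs, "female", "survival.harvest_season"),
                             "survival.harvest_season.female", annual_required=True)
    hsm = _parse_link_normal("HSm", _require(hs, "male", "survival.harvest_season"),
                             "survival.harvest_season.male", annual_required=True)
    ns = _parse_link_normal("NS", _require(surv, "non_harvest", "survival"),
                            "survival.non_harvest", annual_required=True)
    cubsa = _parse_link_normal("CubSa", _require(surv, "cub_a", "survival"), "survival.cub_a")
    cubsb = _parse_link_normal("CubSb", _require(surv, "cub_b", "survival"), "survival.cub_b")
    rep = _parse_link_normal("Rep", _require(surv, "reporting", "survival"), "survival.reporting")

    offsets = raw.get("age_offsets", {})
    offset_sd = float(offsets.get("sd", 1.0))
    n_offsets = int(offsets.get("n_offset_classes", 3))

    init_node = _require(raw, "initial_population", "<root>")
    age_props = np.asarray(
        _require(init_node, "age_class_proportions", "initial_population"), dtype=float
    )
    if age_props.shape != (N_AGE_CLASSES,):
        raise PriorSchemaError(
            f"initial_population.age_class_proportions must have {N_AGE_CLASSES} entries"
        )
    male_frac = float(_require(init_node, "male_fraction", "initial_population"))
    if not 0.0 <= male_frac <= 1.0:
        raise PriorSchemaError("initial_population.male_fraction must lie in [0, 1]")
    props = np.stack([age_props * (1.0 - male_frac), age_props * male_frac], axis=1)
    props = props / props.sum()
    try:
        init = InitialPopulationPrior(
            n_total=float(_require(init_node, "n_total", "initial_population")),
            age_sex_proportions=props,
            dispersion=float(init_node.get("dispersion", 0.2)),
        )
    except (TypeError, ValueError) as exc:
        raise PriorSchemaError(f"invalid value in initial_population: {exc}") from exc

    return DemographicPriors(LS=ls, PR=pr, SP=sp, CubSa=cubsa, CubSb=cubsb,
                             HSf=hsf, HSm=hsm, NS=ns, Rep=rep,
                             initial_population=init,
                             age_offset_sd=offset_sd, n_age_offsets=n_offsets)


def dump_priors(priors: DemographicPriors, path: str | Path) -> None:
    """Write a prior set back out in the packaged YAML schema (lossless)."""

    def bg(spec: PriorSpec) -> dict:
        if spec.family == GAMMA:
            return {"family": "gamma", "shape": float(spec.hyper_a), "rate": float(spec.hyper_b)}
        return {"family": "beta", "alpha": float(spec.hyper_a), "beta": float(spec.hyper_b)}

    def ln(spec: PriorSpec) -> dict:
        node = {"mean": float(spec.real_scale_mean),
                "long_term_precision": float(spec.long_term_precision)}
        if spec.annual_precision_prior is not None:
            shape, rate = spec.annual_precision_prior
            node["annual_precision_prior"] = {"shape": shape, "rate": rate}
        return node

    init = priors.initial_population
    age_props = init.age_sex_proportions.sum(axis=1)
    male_frac = float(init.age_sex_proportions[:, 1].sum())
    doc = {
        "schema_version": 1,
        "recruitment": {
            "litter_size": {g: bg(s) for g, s in zip(FECUNDITY_GROUP_LABELS, priors.LS)},
            "pregnancy_rate": {g: bg(s) for g, s in zip(FECUNDITY_GROUP_LABELS, priors.PR)},
            "sex_proportion_female": bg(priors.SP),
        },
        "survival": {
            "link": "cloglog-mortality",
            "harvest_season": {"female": ln(priors.HSf), "male": ln(priors.HSm)},
            "non_harvest": ln(priors.NS),
            "cub_a": ln(priors.CubSa),
            "cub_b": ln(priors.CubSb),
            "reporting": ln(priors.Rep),
        },
        "age_offsets": {"n_offset_classes": priors.n_age_offsets, "sd": priors.age_offset_sd},
        "initial_population": {
            "n_total": float(init.n_total),
            "dispersion": float(init.dispersion),
            "age_class_proportions": [float(p) for p in age_props],
            "male_fraction": male_frac,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
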