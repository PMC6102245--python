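"""Synthetic harvest registries with known truth.

A stochastic forward run of the population process (year-varying survival
on the link scale) followed by the observation model (Poisson totals, a
binomially thinned aged subset allocated multinomially over age/sex
classes). Every pipeline stage is testable against the recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .observation import HarvestData
from .population import (
    AbundanceArray,
    VitalRates,
    project_abundance,
    survival_from_link,
)
from .priors import DemographicPriors, build_default_priors, prior_mean

__all__ = [
    "FIXTURES",
    "SimulationDesign",
    "SimulationTruth",
    "center_vitals",
    "make_fixture",
    "simulate",
    "simulate_harvest",
    "simulate_truth",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Knobs of the generator; defaults emulate the study system."""

    n_years: int = 8                  # harvest years
    first_year: int = 2009
    initial_total: float = 21_450.0
    n_age_classes: int = 10
    annual_sd_link: float = 0.158     # spread of year effects on the link scale
    aging_rate: float = 0.859         # fraction of the harvest aged and sexed
    seed: int = 0
    deterministic_observation: bool = False

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("the two-year recruitment lag needs at least 3 years")
        if not 0.0 < self.aging_rate <= 1.0:
            raise ValueError("aging_rate must lie in (0, 1]")
        if self.annual_sd_link < 0:
            raise ValueError("annual_sd_link must be nonnegative")
        if self.initial_total <= 0:
            raise ValueError("initial_total must be positive")


@dataclass
class SimulationTruth:
    """Truth ledger of one simulated population."""

    vitals: VitalRates
    abundance: AbundanceArray            # (A, 2, n_years + 1)
    expected_kills: np.ndarray           # (A, 2, n_years)
    seed: int


def center_vitals(design: SimulationDesign,
                  priors: DemographicPriors | None = None,
                  rng: np.random.Generator | None = None) -> VitalRates:
    """Vital rates at the packaged prior means, with seeded year effects.

    Year effects are normal on the survival link scale with spread
    ``design.annual_sd_link`` (zero spread gives the deterministic center).
    """
    priors = priors or build_default_priors()
    rng = rng or np.random.default_rng(design.seed)
    Y, A = design.n_years, design.n_age_classes
    eps_hs = rng.normal(0.0, design.annual_sd_link, size=Y) if design.annual_sd_link else np.zeros(Y)
    eps_ns = rng.normal(0.0, design.annual_sd_link, size=Y) if design.annual_sd_link else np.zeros(Y)
    mu = np.array([priors.HSf.link_mean, priors.HSm.link_mean])
    HS = survival_from_link(mu[None, :, None] + eps_hs[None, None, :]
                            + np.zeros(A)[:, None, None])
    NS = survival_from_link(priors.NS.link_mean + eps_ns)
    return VitalRates(
        LS=np.array([prior_mean(s) for s in priors.LS]),
        PR=np.array([prior_mean(s) for s in priors.PR]),
        SP=np.array([prior_mean(priors.SP), 1.0 - prior_mean(priors.SP)]),
        CubSa=prior_mean(priors.CubSa),
        CubSb=prior_mean(priors.CubSb),
        HS=HS,
        NS=NS,
        Rep=np.array([prior_mean(priors.Rep)] * 2),
        LHR=np.zeros(3),
    )


def simulate_truth(design: SimulationDesign,
                   priors: DemographicPriors | None = None) -> SimulationTruth:
    """Forward-run the population process; deterministic given the seed."""
    priors = priors or build_default_priors()
    rng = np.random.default_rng(design.seed)
    vitals = center_vitals(design, priors, rng)
    A = design.n_age_classes
    props = np.asarray(priors.initial_population.age_sex_proportions, dtype=float)
    if props.shape[0] != A:
        # collapse/renormalize the packaged 10-class proportions onto A classes
        age = props.sum(axis=1)
        sex = props.sum(axis=0) / props.sum()
        age = np.concatenate([age[:A - 1], [age[A - 1:].sum()]])
        props = np.outer(age, sex)
    initial = design.initial_total * props / props.sum()
    abundance = project_abundance(initial, vitals, design.n_years + 1,
                                  first_year=design.first_year)
    assert np.all(abundance.values >= 0)
    HR = vitals.HR
    expected = abundance.values[:, :, :design.n_years] * HR
    return SimulationTruth(vitals=vitals, abundance=abundance,
                           expected_kills=expected, seed=design.seed)


def simulate_harvest(truth: SimulationTruth, design: SimulationDesign) -> HarvestData:
    """Observe the truth: registry totals and the aged/sexed subset.

    ``O_y`` is Poisson around the summed expected kills; the aged subset
    is ``Binomial(O_y, aging_rate)`` (aging failure independent of class)
    allocated multinomially by expected-kill shares, so ``O >= sum(C)``
    holds by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    A, _, Y = truth.expected_kills.shape
    O = np.zeros(Y, dtype=int)
    C = np.zeros((A, 2, Y), dtype=int)
    for y in range(Y):
        H = truth.expected_kills[:, :, y]
        total = float(H.sum())
        if design.deterministic_observation:
            C[:, :, y] = np.rint(H * design.aging_rate).astype(int)
            if design.aging_rate == 1.0:
                O[y] = int(C[:, :, y].sum())   # complete aging: O == sum(C)
            else:
                O[y] = max(int(np.rint(total)), int(C[:, :, y].sum()))
            continue
        if total <= 0:
            continue
        O[y] = rng.poisson(total)
        n_aged = rng.binomial(O[y], design.aging_rate)
        if n_aged > 0:
            C[:, :, y] = rng.multinomial(n_aged, (H / total).reshape(-1)).reshape(A, 2)
    years = design.first_year + np.arange(Y)
    return HarvestData(years=years, O=O, C=C)


def simulate(design: SimulationDesign,
             priors: DemographicPriors | None = None) -> tuple[HarvestData, SimulationTruth]:
    truth = simulate_truth(design, priors)
    return simulate_harvest(truth, design), truth


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURES: dict[str, SimulationDesign] = {
    # 8 harvest years shaped like the study registry: totals in the low
    # thousands, ~86% of kills aged and sexed
    "paper_shape": SimulationDesign(),
    # small instance for oracle tests: 3 age classes, 3 years, totals < 100
    "tiny_3class": SimulationDesign(n_years=3, n_age_classes=3, initial_total=240.0,
                                    annual_sd_link=0.1),
    # noise-free: deterministic expected kills rounded, complete aging
    "no_noise": SimulationDesign(annual_sd_link=0.0, aging_rate=1.0,
                                 deterministic_observation=True),
}


def make_fixture(name: str, out_dir: str | Path, seed: int | None = None
                 ) -> tuple[HarvestData, SimulationTruth]:
    """Generate a registered fixture and write registry CSV + truth JSON."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    design = FIXTURES[name]
    if seed is not None:
        design = replace(design, seed=seed)
    data, truth = simulate(design)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_registry

    write_registry(data, out_dir / f"{name}_registry.csv")
    truth_doc = {
        "fixture": name,
        "seed": design.seed,
        "design": {
            "n_years": design.n_years,
            "first_year": design.first_year,
            "initial_total": design.initial_total,
            "n_age_classes": design.n_age_classes,
            "annual_sd_link": design.annual_sd_link,
            "aging_rate": design.aging_rate,
        },
        "vitals": {
            "LS": truth.vitals.LS.tolist(),
            "PR": truth.vitals.PR.tolist(),
            "SP": truth.vitals.SP.tolist(),
            "CubSa": float(truth.vitals.CubSa),
            "CubSb": float(truth.vitals.CubSb),
            "Rep": truth.vitals.Rep.tolist(),
            "NS": truth.vitals.NS.tolist(),
            "HS_year_mean": truth.vitals.HS.mean(axis=(0, 1)).tolist(),
        },
        "abundance_total_by_year": truth.abundance.total_by_year().tolist(),
        "years": truth.abundance.year_labels.tolist(),
    }
    with open(out_dir / f"{name}_truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2)
    return data, truth
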