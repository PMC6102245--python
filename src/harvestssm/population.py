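"""Deterministic skeleton of the population process.

Two-sex, multi-stage projection with harvest and non-harvest survival,
age-specific fecundity with a two-year recruitment lag, an absorbing
terminal age class, and cub back-calculation.

Conventions used throughout the package:

* age classes are indexed ``0..A-1`` and correspond to ages
  ``1.5, 2.5, ..., (A-0.5)+`` years (the last class is absorbing);
* sex index 0 is female, 1 is male;
* abundance is pre-season (immediately preceding the hunting season);
* the survival link is a complementary log-log applied to mortality,
  so ``link(s) = log(-log(s))`` and positive link-scale offsets
  *increase* mortality (decrease survival).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEMALE",
    "MALE",
    "SEX_LABELS",
    "N_AGE_CLASSES",
    "AGE_CLASS_LABELS",
    "FECUNDITY_GROUP_LABELS",
    "AbundanceArray",
    "VitalRates",
    "age_class_labels",
    "annual_survival",
    "back_calculate_cubs",
    "fecundity",
    "fecundity_group_index",
    "harvest_rate",
    "initialize_abundance",
    "project_abundance",
    "survival_from_effects",
    "survival_from_link",
    "survival_to_link",
]

FEMALE = 0
MALE = 1
SEX_LABELS = ("F", "M")

#: Number of harvestable age classes in the full model (1.5 .. 10.5+).
N_AGE_CLASSES = 10

#: Age groups over which litter size and pregnancy rate are defined.
FECUNDITY_GROUP_LABELS = ("2.5", "3.5", "4.5", "5.5+")


def age_class_labels(n_age_classes: int = N_AGE_CLASSES) -> tuple[str, ...]:
    """Labels ``"1.5", "2.5", ..., "<a>.5+"`` for the age classes."""
    if n_age_classes < 2:
        raise ValueError("need at least two age classes")
    labels = [f"{a + 1.5:g}" for a in range(n_age_classes - 1)]
    labels.append(f"{n_age_classes + 0.5:g}+")
    return tuple(labels)


AGE_CLASS_LABELS = age_class_labels()


def fecundity_group_index(n_age_classes: int = N_AGE_CLASSES) -> np.ndarray:
    """Map age-class index -> fecundity group index (or -1 for no breeding).

    Class 0 (1.5-year-olds) produces no cubs; classes 1, 2, 3 map to the
    2.5 / 3.5 / 4.5 groups and every older class to the 5.5+ group.
    """
    idx = np.full(n_age_classes, -1, dtype=np.int64)
    for a in range(1, n_age_classes):
        idx[a] = min(a - 1, 3)
    return idx


# ---------------------------------------------------------------------------
# survival link
# ---------------------------------------------------------------------------

def survival_to_link(s):
    """Forward link: ``log(-log(s))`` for survival ``s`` in (0, 1)."""
    s = np.asarray(s, dtype=float)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("survival must lie strictly in (0, 1) on the link scale")
    out = np.log(-np.log(s))
    return float(out) if out.ndim == 0 else out


def survival_from_link(eta):
    """Inverse link: ``exp(-exp(eta))``, mapping all reals into (0, 1)."""
    out = np.exp(-np.exp(np.asarray(eta, dtype=float)))
    return float(out) if out.ndim == 0 else out


def survival_from_effects(sex_mean_link: float, year_effect: float = 0.0,
                          age_offset: float = 0.0):
    """Harvest-season survival from additive link-scale effects.

    Monotone decreasing in each term: positive effects raise mortality.
    """
    return survival_from_link(
        np.asarray(sex_mean_link, dtype=float)
        + np.asarray(year_effect, dtype=float)
        + np.asarray(age_offset, dtype=float)
    )


# ---------------------------------------------------------------------------
# elementary demographic quantities
# ---------------------------------------------------------------------------

def fecundity(litter_size, pregnancy_rate):
    """Per-female cub production, ``LS * PR`` (cub survival applied later).

    Cub survival to recruitment is deliberately *not* folded in here; it is
    applied exactly once, in the recruitment term of :func:`project_abundance`.
    """
    ls = np.asarray(litter_size, dtype=float)
    pr = np.asarray(pregnancy_rate, dtype=float)
    if np.any(ls < 0) or np.any(pr < 0):
        raise ValueError("litter size and pregnancy rate must be nonnegative")
    if np.any(pr > 1):
        raise ValueError("pregnancy rate must be at most 1")
    out = ls * pr
    return float(out) if out.ndim == 0 else out


def harvest_rate(harvest_survival, reporting_rate):
    """Harvest rate ``HR = (1 - HS) * Rep``.

    The season mortality ``1 - HS`` partitions exactly into the reported
    harvest ``(1 - HS) * Rep`` and unreported loss ``(1 - HS) * (1 - Rep)``.
    """
    hs = np.asarray(harvest_survival, dtype=float)
    rep = np.asarray(reporting_rate, dtype=float)
    if np.any((hs < 0) | (hs > 1)) or np.any((rep < 0) | (rep > 1)):
        raise ValueError("survival and reporting rate must lie in [0, 1]")
    out = (1.0 - hs) * rep
    return float(out) if out.ndim == 0 else out


def annual_survival(harvest_survival, nonharvest_survival):
    """Annual survival ``S = HS * NS``."""
    hs = np.asarray(harvest_survival, dtype=float)
    ns = np.asarray(nonharvest_survival, dtype=float)
    if np.any((hs < 0) | (hs > 1)) or np.any((ns < 0) | (ns > 1)):
        raise ValueError("seasonal survivals must lie in [0, 1]")
    out = hs * ns
    return float(out) if out.ndim == 0 else out


def back_calculate_cubs(n_yearlings_next, cub_survival_b):
    """Back-calculate 0.5-year-olds: ``N_{0.5,s,y-1} = N_{1.5,s,y} / CubSb``."""
    if not cub_survival_b > 0:
        raise ZeroDivisionError("CubSb must be positive to back-calculate cubs")
    n = np.asarray(n_yearlings_next, dtype=float)
    if np.any(n < 0):
        raise ValueError("abundance must be nonnegative")
    out = n / float(cub_survival_b)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VitalRates:
    """One realization of every demographic parameter.

    ``HS`` has shape ``(A, 2, Y)``; ``NS`` has shape ``(Y,)``; the rest are
    small vectors or scalars. Derived quantities (``fec``, ``HR``, ``S``)
    are exposed as properties.
    """

    LS: np.ndarray            # (4,) litter size per fecundity group
    PR: np.ndarray            # (4,) pregnancy rate per fecundity group
    SP: np.ndarray            # (2,) newborn sex proportions (F, M)
    CubSa: float              # cub survival, birth -> first season
    CubSb: float              # cub survival, first -> second season
    HS: np.ndarray            # (A, 2, Y) harvest-season survival
    NS: np.ndarray            # (Y,) non-harvest-season survival
    Rep: np.ndarray           # (2,) reporting rate (F, M)
    LHR: np.ndarray = field(default_factory=lambda: np.zeros(3))  # link offsets

    def __post_init__(self) -> None:
        self.LS = np.asarray(self.LS, dtype=float)
        self.PR = np.asarray(self.PR, dtype=float)
        self.SP = np.asarray(self.SP, dtype=float)
        self.HS = np.asarray(self.HS, dtype=float)
        self.NS = np.asarray(self.NS, dtype=float)
        self.Rep = np.asarray(self.Rep, dtype=float)
        self.LHR = np.asarray(self.LHR, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.LS.shape != (4,) or np.any(self.LS <= 0):
            raise ValueError("LS must be 4 positive litter sizes")
        for name in ("PR", "SP", "Rep"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.PR.shape != (4,):
            raise ValueError("PR must have 4 fecundity groups")
        if abs(float(self.SP.sum()) - 1.0) > 1e-9:
            raise ValueError("sex proportions must sum to 1")
        for name in ("CubSa", "CubSb"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.HS.ndim != 3 or self.HS.shape[1] != 2:
            raise ValueError("HS must have shape (A, 2, Y)")
        if np.any((self.HS < 0) | (self.HS > 1)) or np.any((self.NS < 0) | (self.NS > 1)):
            raise ValueError("seasonal survivals must lie in [0, 1]")
        if self.NS.shape != (self.HS.shape[2],):
            raise ValueError("NS must have one value per HS year")

    @property
    def n_age_classes(self) -> int:
        return self.HS.shape[0]

    @property
    def n_years(self) -> int:
        return self.HS.shape[2]

    @property
    def fec(self) -> np.ndarray:
        """Per-female cub production per fecundity group, ``LS * PR``."""
        return fecundity(self.LS, self.PR)

    @property
    def fec_by_class(self) -> np.ndarray:
        """Fecundity mapped onto age classes (0 for the first class)."""
        gidx = fecundity_group_index(self.n_age_classes)
        out = np.zeros(self.n_age_classes)
        breeding = gidx >= 0
        out[breeding] = self.fec[gidx[breeding]]
        return out

    @property
    def HR(self) -> np.ndarray:
        """Harvest rate ``(1 - HS) * Rep``, shape ``(A, 2, Y)``."""
        return harvest_rate(self.HS, self.Rep[None, :, None])

    @property
    def S(self) -> np.ndarray:
        """Annual survival ``HS * NS``, shape ``(A, 2, Y)``."""
        return annual_survival(self.HS, self.NS[None, None, :])


@dataclass
class AbundanceArray:
    """Latent pre-season abundance ``N[a, s, y]`` plus year labels."""

    values: np.ndarray                 # (A, 2, Y)
    year_labels: np.ndarray            # (Y,) calendar years
    cubs: np.ndarray | None = None     # (2, Y) optional back-calculated 0.5-olds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.year_labels = np.asarray(self.year_labels, dtype=int)
        if self.values.ndim != 3 or self.values.shape[1] != 2:
            raise ValueError("values must have shape (A, 2, Y)")
        if np.any(self.values < 0):
            raise ValueError("abundance must be nonnegative")
        if self.year_labels.shape != (self.values.shape[2],):
            raise ValueError("one year label per abundance year is required")

    @property
    def n_years(self) -> int:
        return self.values.shape[2]

    @property
    def n_age_classes(self) -> int:
        return self.values.shape[0]

    def total_by_year(self) -> np.ndarray:
        return self.values.sum(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long frame: year, sex, age_class, abundance."""
        A, _, Y = self.values.shape
        labels = age_class_labels(A)
        records = []
        for y in range(Y):
            for s in range(2):
                for a in range(A):
                    records.append(
                        {
                            "year": int(self.year_labels[y]),
                            "sex": SEX_LABELS[s],
                            "age_class": labels[a],
                            "abundance": self.values[a, s, y],
                        }
                    )
        return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_abundance(initial, vitals: VitalRates, n_years: int,
                      first_year: int = 2009) -> AbundanceArray:
    """Project abundance forward through ``n_years`` pre-season censuses.

    ``initial`` is the year-1 slice, shape ``(A, 2)``. For years ``y >= 2``:

    * interior classes age forward: ``N[a] = N[a-1] * S[a-1]`` of the
      previous year;
    * the terminal class absorbs: survivors of the two oldest classes;
    * the first class receives recruits produced by the females alive two
      years earlier, ``SP_s * CubSa * CubSb * sum_a N[a, F, y-2] * Fec_a``,
      with the lag clamped to ``y-1`` when ``y-2`` precedes the series.

    ``vitals`` must provide survivals for at least ``n_years - 1`` years.
    """
    if n_years < 2:
        raise ValueError("projection requires at least two years")
    initial = np.asarray(initial, dtype=float)
    A = vitals.n_age_classes
    if initial.shape != (A, 2):
        raise ValueError(f"initial slice must have shape ({A}, 2)")
    if np.any(initial < 0):
        raise ValueError("initial abundance must be nonnegative")
    if vitals.n_years < n_years - 1:
        raise ValueError("vital rates cover too few years for this projection")

    S = vitals.S
    if np.any(S < 0):
        raise ValueError("negative survival product")
    fec = vitals.fec_by_class
    cub_survival = float(vitals.CubSa) * float(vitals.CubSb)

    N = np.zeros((A, 2, n_years))
    N[:, :, 0] = initial
    for y in range(1, n_years):
        lag = y - 2 if y >= 2 else y - 1
        recruits = cub_survival * float(N[:, FEMALE, lag] @ fec)
        N[0, :, y] = vitals.SP * recruits
        N[1:A - 1, :, y] = N[0:A - 2, :, y - 1] * S[0:A - 2, :, y - 1]
        N[A - 1, :, y] = (
            N[A - 2, :, y - 1] * S[A - 2, :, y - 1]
            + N[A - 1, :, y - 1] * S[A - 1, :, y - 1]
        )
    years = first_year + np.arange(n_years)
    return AbundanceArray(values=N, year_labels=years)


def initialize_abundance(prior) -> np.ndarray:
    """Year-1 abundance slice: ``n_total`` allocated by the prior proportions.

    ``prior`` is an :class:`~harvestssm.priors.InitialPopulationPrior`.
    Returns a real-valued ``(A, 2)`` slice summing to ``n_total``.
    """
    props = np.asarray(prior.age_sex_proportions, dtype=float)
    if props.ndim != 2 or props.shape[1] != 2:
        raise ValueError("age_sex_proportions must have shape (A, 2)")
    if np.any(props < 0) or abs(float(props.sum()) - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    return float(prior.n_total) * props
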