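"""Two-part harvest observation model.

The total registered harvest ``O_y`` is Poisson around the expected kills
``sum_{a,s} N * HR``; the aged-and-sexed subset ``C`` is multinomial over
age/sex classes with probabilities proportional to expected kills,
conditioned on the aged subset size (which is treated as ancillary).
A binomial variant for ``O`` is available as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .population import AbundanceArray, VitalRates, age_class_labels

__all__ = [
    "HarvestData",
    "expected_harvest",
    "joint_loglik",
    "loglik_agesex",
    "loglik_total",
]


@dataclass
class HarvestData:
    """Observed harvest registry: the model's only data.

    ``O`` holds the total registered harvest per year (a complete count,
    including animals that could not be aged or sexed); ``C`` holds the
    aged/sexed counts by age class (cubs excluded — they cannot legally be
    harvested), sex and year.
    """

    years: np.ndarray            # (Y,) calendar years
    O: np.ndarray                # (Y,) total registered harvest
    C: np.ndarray                # (A, 2, Y) aged/sexed counts
    permits: np.ndarray | None = None   # (Y,) optional permit counts for CPUE

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.O = np.asarray(self.O, dtype=int)
        self.C = np.asarray(self.C, dtype=int)
        if self.permits is not None:
            self.permits = np.asarray(self.permits, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.C.ndim != 3 or self.C.shape[1] != 2:
            raise ValueError("C must have shape (A, 2, Y)")
        Y = self.C.shape[2]
        if self.years.shape != (Y,) or self.O.shape != (Y,):
            raise ValueError("years, O and C must agree on the number of years")
        if np.any(self.O < 0) or np.any(self.C < 0):
            raise ValueError("harvest counts must be nonnegative")
        aged = self.C.sum(axis=(0, 1))
        bad = np.nonzero(aged > self.O)[0]
        if bad.size:
            raise ValueError(
                f"aged/sexed counts exceed the registered total in year {int(self.years[bad[0]])}"
            )
        if self.permits is not None:
            if self.permits.shape != (Y,) or np.any(self.permits <= 0):
                raise ValueError("permits must be positive, one per year")

    @property
    def n_years(self) -> int:
        return self.C.shape[2]

    @property
    def n_age_classes(self) -> int:
        return self.C.shape[0]

    @property
    def n_aged(self) -> np.ndarray:
        """Aged/sexed subset size per year."""
        return self.C.sum(axis=(0, 1))

    @property
    def aged_fraction(self) -> np.ndarray:
        """Per-year fraction of the registered harvest with known age and sex."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.O > 0, self.n_aged / self.O, np.nan)

    @property
    def age_labels(self) -> tuple[str, ...]:
        return age_class_labels(self.n_age_classes)


def expected_harvest(N_slice: np.ndarray, HR_slice: np.ndarray) -> np.ndarray:
    """Expected kills ``H = N * HR`` elementwise for one year."""
    N_slice = np.asarray(N_slice, dtype=float)
    HR_slice = np.asarray(HR_slice, dtype=float)
    if N_slice.shape != HR_slice.shape:
        raise ValueError("abundance and harvest-rate slices must share a shape")
    if np.any((HR_slice < 0) | (HR_slice > 1)):
        raise ValueError("harvest rates must lie in [0, 1]")
    if np.any(N_slice < 0):
        raise ValueError("abundance must be nonnegative")
    return N_slice * HR_slice


def loglik_total(O_y: int, H_y_total: float, family: str = "poisson") -> float:
    """Log-probability of the registered total ``O_y`` given expected kills.

    Poisson with mean ``H_y_total``. ``H = 0`` with ``O > 0`` is an
    impossible-data signal and returns ``-inf`` rather than raising.
    """
    if O_y < 0:
        raise ValueError("observed harvest must be nonnegative")
    if H_y_total < 0:
        raise ValueError("expected kills must be nonnegative")
    if family != "poisson":
        raise ValueError(f"unsupported total-harvest family: {family!r}")
    if H_y_total == 0.0:
        return 0.0 if O_y == 0 else -np.inf
    return float(O_y * np.log(H_y_total) - H_y_total - gammaln(O_y + 1.0))


def loglik_agesex(C_y: np.ndarray, H_y: np.ndarray) -> float:
    """Multinomial log-probability of the aged/sexed counts for one year.

    Class probabilities are the expected-kill shares ``H / sum(H)``; the
    subset size ``n = sum(C_y)`` is conditioned on. A zero-probability
    class with a positive count yields ``-inf``.
    """
    C_y = np.asarray(C_y, dtype=float)
    H_y = np.asarray(H_y, dtype=float)
    if C_y.shape != H_y.shape:
        raise ValueError("counts and expected kills must share a shape")
    if np.any(C_y < 0) or np.any(H_y < 0):
        raise ValueError("counts and expected kills must be nonnegative")
    n = C_y.sum()
    if n == 0:
        return 0.0
    total = H_y.sum()
    if total <= 0:
        return -np.inf
    p = H_y / total
    if np.any((p == 0) & (C_y > 0)):
        return -np.inf
    return float(gammaln(n + 1.0) - gammaln(C_y + 1.0).sum() + xlogy(C_y, p).sum())


def joint_loglik(data: HarvestData, N: AbundanceArray, vitals: VitalRates) -> float:
    """Sum over years of the total-harvest and aged/sexed log-likelihoods.

    The likelihood factorizes over years given the abundance trajectory,
    so it is invariant to the order in which years are visited.
    """
    Y = data.n_years
    if N.n_years < Y or vitals.n_years < Y:
        raise ValueError("abundance and vital rates must cover every data year")
    if N.n_age_classes != data.n_age_classes:
        raise ValueError("abundance and data disagree on the number of age classes")
    HR = vitals.HR
    lp = 0.0
    for y in range(Y):
        H = expected_harvest(N.values[:, :, y], HR[:, :, y])
        lp += loglik_total(int(data.O[y]), float(H.sum()))
        lp += loglik_agesex(data.C[:, :, y], H)
    return float(lp)
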