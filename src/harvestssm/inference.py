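"""Posterior sampling for the age-at-harvest state-space model.

The sampler is an adaptive random-walk Metropolis-within-Gibbs over
parameter blocks (recruitment, reporting, harvest-survival structure,
harvest-survival year effects, non-harvest survival, initial abundance).
Proposal scales and covariances adapt during burn-in only, so the
retained draws form a valid Markov chain. Latent abundance is a
deterministic function of the sampled parameters and is integrated out by
construction rather than sampled cell by cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logit

from . import _core
from .observation import HarvestData
from .population import (
    AbundanceArray,
    VitalRates,
    fecundity_group_index,
    survival_from_link,
)
from .priors import DemographicPriors

__all__ = [
    "AgeAtHarvestModel",
    "MCMCConfig",
    "PosteriorSamples",
    "adaptive_block_metropolis",
    "desk_config",
    "gelman_rubin",
    "posterior_summary",
    "run_mcmc",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration; defaults follow the full production run."""

    n_iterations: int = 220_000
    n_chains: int = 3
    burn_in: int = 20_000
    thin: int = 4
    seed: int = 0
    rhat_threshold: float = 1.1
    target_accept: float = 0.35
    init_scale: float = 0.1
    max_init_retries: int = 100

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: floor((n_iterations - burn_in) / thin)."""
        return (self.n_iterations - self.burn_in) // self.thin


def desk_config(seed: int = 0, **overrides) -> MCMCConfig:
    """Scaled-down configuration used for tests and desk runs."""
    base = MCMCConfig(n_iterations=20_000, n_chains=3, burn_in=10_000, thin=4, seed=seed)
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

class AgeAtHarvestModel:
    """Packs data and priors into the flat arrays the numerical core consumes."""

    def __init__(self, data: HarvestData, priors: DemographicPriors,
                 first_year: int | None = None):
        self.data = data
        self.priors = priors
        self.Y = data.n_years
        self.A = data.n_age_classes
        if self.A < _core.N_LHR + 1:
            raise ValueError("model needs more age classes than age offsets")
        prop0 = np.asarray(priors.initial_population.age_sex_proportions, dtype=float)
        if prop0.shape != (self.A, 2):
            raise ValueError(
                f"initial-population proportions have shape {prop0.shape}, "
                f"expected ({self.A}, 2)"
            )
        self.prop0 = prop0
        self.fecmap = fecundity_group_index(self.A)
        self.O = data.O.astype(float)
        self.C = data.C.astype(float)
        self.lgam_C = gammaln(self.C + 1.0).sum(axis=(0, 1))
        self.first_year = int(data.years[0]) if first_year is None else int(first_year)
        self.hp = self._pack_hyperparameters()
        self.dim = _core.theta_dim(self.Y)
        self.param_names = self._names()

    def _pack_hyperparameters(self) -> np.ndarray:
        p = self.priors
        hp = np.empty(_core.HP_SIZE)
        for i, spec in enumerate(p.LS):
            hp[_core.HP_LS_SHAPE + i] = spec.hyper_a
            hp[_core.HP_LS_RATE + i] = spec.hyper_b
        for i, spec in enumerate(p.PR):
            hp[_core.HP_PR_ALPHA + i] = spec.hyper_a
            hp[_core.HP_PR_BETA + i] = spec.hyper_b
        hp[_core.HP_SP_ALPHA] = p.SP.hyper_a
        hp[_core.HP_SP_BETA] = p.SP.hyper_b
        for base, spec in ((_core.HP_CUBSA, p.CubSa), (_core.HP_CUBSB, p.CubSb),
                           (_core.HP_REP, p.Rep), (_core.HP_HSF, p.HSf),
                           (_core.HP_HSM, p.HSm), (_core.HP_NS, p.NS)):
            hp[base] = spec.link_mean
            hp[base + 1] = spec.long_term_precision
        # one shared annual-precision hyperprior (HS and NS year effects)
        hp[_core.HP_ANNPREC] = p.HSf.annual_precision_prior[0]
        hp[_core.HP_ANNPREC + 1] = p.HSf.annual_precision_prior[1]
        hp[_core.HP_LHR_SD] = p.age_offset_sd
        hp[_core.HP_LOGN0_MEAN] = math.log(p.initial_population.n_total)
        hp[_core.HP_LOGN0_SD] = p.initial_population.dispersion
        return hp

    def _names(self) -> list[str]:
        years = [str(self.first_year + y) for y in range(self.Y)]
        names = [f"log_LS_{g}" for g in ("2.5", "3.5", "4.5", "5.5+")]
        names += [f"logit_PR_{g}" for g in ("2.5", "3.5", "4.5", "5.5+")]
        names += ["logit_SP_f", "eta_CubSa", "eta_CubSb", "eta_Rep_F", "eta_Rep_M",
                  "mu_HS_F", "dlt_HS_M"]
        names += [f"a_HS_{y}" for y in years]
        names += ["log_tau_HS", "mu_NS"]
        names += [f"a_NS_{y}" for y in years]
        names += ["log_tau_NS", "LHR_1", "LHR_2", "LHR_3", "log_N0"]
        return names

    # -- densities ---------------------------------------------------------

    def log_posterior(self, theta: np.ndarray) -> float:
        """Joint log-posterior; ``-inf`` (never an exception) off-support."""
        theta = np.asarray(theta, dtype=float)
        try:
            return float(_core._log_post(theta, self.O, self.C, self.lgam_C,
                                         self.prop0, self.fecmap, self.hp,
                                         self.Y, self.A))
        except OverflowError:  # pure-python fallback without IEEE semantics
            return -np.inf

    # -- parameter mapping -------------------------------------------------

    def initial_theta(self, rng: np.random.Generator) -> np.ndarray:
        """Over-dispersed initial point: an independent draw from the priors."""
        p = self.priors
        Y = self.Y
        theta = np.empty(self.dim)
        for i, spec in enumerate(p.LS):
            theta[i] = math.log(rng.gamma(spec.hyper_a, 1.0 / spec.hyper_b))
        for i, spec in enumerate(p.PR):
            theta[4 + i] = logit(rng.beta(spec.hyper_a, spec.hyper_b))
        theta[8] = logit(rng.beta(p.SP.hyper_a, p.SP.hyper_b))
        for idx, spec in ((9, p.CubSa), (10, p.CubSb), (11, p.Rep), (12, p.Rep),
                          (13, p.HSf)):
            theta[idx] = rng.normal(spec.link_mean, spec.link_sd)
        theta[14] = rng.normal(p.HSm.link_mean, p.HSm.link_sd) - theta[13]
        shape, rate = p.HSf.annual_precision_prior
        tau_hs = rng.gamma(shape, 1.0 / rate)
        theta[15:15 + Y] = rng.normal(theta[13], 1.0 / math.sqrt(tau_hs), size=Y)
        theta[15 + Y] = math.log(tau_hs)
        theta[16 + Y] = rng.normal(p.NS.link_mean, p.NS.link_sd)
        tau_ns = rng.gamma(shape, 1.0 / rate)
        theta[17 + Y:17 + 2 * Y] = rng.normal(theta[16 + Y], 1.0 / math.sqrt(tau_ns), size=Y)
        theta[17 + 2 * Y] = math.log(tau_ns)
        theta[18 + 2 * Y:21 + 2 * Y] = rng.normal(0.0, p.age_offset_sd, size=_core.N_LHR)
        init = p.initial_population
        theta[21 + 2 * Y] = rng.normal(math.log(init.n_total), init.dispersion)
        return theta

    def vitals_from_theta(self, theta: np.ndarray) -> VitalRates:
        """Real-scale vital rates (pure numpy; independent of the JIT core)."""
        Y, A = self.Y, self.A
        theta = np.asarray(theta, dtype=float)
        LS = np.exp(theta[0:4])
        PR = 1.0 / (1.0 + np.exp(-theta[4:8]))
        spf = 1.0 / (1.0 + np.exp(-theta[8]))
        levels = theta[15:15 + Y]
        sex_delta = np.array([0.0, theta[14]])
        lhr = np.zeros(A)
        lhr[:_core.N_LHR] = theta[18 + 2 * Y:21 + 2 * Y]
        HS = survival_from_link(
            levels[None, None, :] + sex_delta[None, :, None] + lhr[:, None, None]
        )
        NS = survival_from_link(theta[17 + Y:17 + 2 * Y])
        return VitalRates(
            LS=LS, PR=PR, SP=np.array([spf, 1.0 - spf]),
            CubSa=survival_from_link(theta[9]), CubSb=survival_from_link(theta[10]),
            HS=HS, NS=NS,
            Rep=survival_from_link(theta[11:13]),
            LHR=theta[18 + 2 * Y:21 + 2 * Y],
        )

    def abundance(self, theta: np.ndarray) -> AbundanceArray:
        """Latent abundance implied by ``theta`` (data years plus one)."""
        N = _core._project(np.asarray(theta, dtype=float), self.prop0,
                           self.fecmap, self.Y, self.A)
        years = self.first_year + np.arange(self.Y + 1)
        return AbundanceArray(values=np.asarray(N), year_labels=years)

    def prior_center_theta(self) -> np.ndarray:
        """Theta at the prior centres (year levels at their long-term means)."""
        p = self.priors
        Y = self.Y
        theta = np.empty(self.dim)
        theta[0:4] = [math.log(s.real_scale_mean) for s in p.LS]
        theta[4:8] = [logit(s.real_scale_mean) for s in p.PR]
        theta[8] = logit(p.SP.real_scale_mean)
        theta[9] = p.CubSa.link_mean
        theta[10] = p.CubSb.link_mean
        theta[11] = theta[12] = p.Rep.link_mean
        theta[13] = p.HSf.link_mean
        theta[14] = p.HSm.link_mean - p.HSf.link_mean
        theta[15:15 + Y] = p.HSf.link_mean
        shape, rate = p.HSf.annual_precision_prior
        theta[15 + Y] = math.log(shape / rate)
        theta[16 + Y] = p.NS.link_mean
        theta[17 + Y:17 + 2 * Y] = p.NS.link_mean
        theta[17 + 2 * Y] = math.log(shape / rate)
        theta[18 + 2 * Y:21 + 2 * Y] = 0.0
        theta[21 + 2 * Y] = math.log(p.initial_population.n_total)
        return theta

    def laplace_approximation(self) -> tuple[np.ndarray, np.ndarray]:
        """MAP point and covariance from a Laplace approximation.

        Used to precondition the sampler's proposal covariances and to
        over-disperse the chain starting points around the posterior mode;
        the target density is untouched, so a rough approximation (clipped
        to positive definiteness) is sufficient.
        """
        from scipy import optimize

        neg = lambda th: -self.log_posterior(th)
        res = optimize.minimize(neg, self.prior_center_theta(), method="L-BFGS-B",
                                options={"maxiter": 1000, "maxfun": 200_000})
        x = res.x
        d = x.size
        h = 1e-4 * np.maximum(np.abs(x), 0.1)
        H = np.empty((d, d))
        f0 = neg(x)
        # central second differences
        fp = np.empty(d)
        fm = np.empty(d)
        for i in range(d):
            e = np.zeros(d)
            e[i] = h[i]
            fp[i] = neg(x + e)
            fm[i] = neg(x - e)
            H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = neg(x + ei + ej)
                fmm = neg(x - ei - ej)
                H[i, j] = H[j, i] = (
                    fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
                ) / (2.0 * h[i] * h[j])
        H = 0.5 * (H + H.T)
        w, V = np.linalg.eigh(H)
        w = np.clip(w, 1e-4 * np.abs(w).max(), None)
        return x, (V / w) @ V.T

    def blocks(self) -> tuple[tuple[str, np.ndarray], ...]:
        # The initial total, harvest-survival year levels, sex contrast and
        # age offsets ride a narrow likelihood ridge (abundance x kill rate
        # ~ observed kills), so they form one covariance-adapted block; the
        # hierarchical means and precisions only touch the prior terms and
        # mix quickly in a small block of their own.
        Y = self.Y
        return (
            ("recruitment", np.arange(0, 11)),
            ("reporting", np.array([11, 12])),
            ("harvest_scale", np.concatenate([np.arange(15, 15 + Y), [14],
                                              np.arange(18 + 2 * Y, 22 + 2 * Y)])),
            ("ns_year_levels", np.arange(17 + Y, 17 + 2 * Y)),
            ("hyper_means", np.array([13, 16 + Y])),
            ("precisions", np.array([15 + Y, 17 + 2 * Y])),
            # joint moves across every parameter: pick up the cross-block
            # correlations the conditional blocks cannot traverse; run twice
            # per sweep (independent adaptive states) for extra ridge travel
            ("global", np.arange(self.dim)),
            ("global2", np.arange(self.dim)),
        )


# ---------------------------------------------------------------------------
# generic sampler
# ---------------------------------------------------------------------------

def adaptive_block_metropolis(logpost, x0: np.ndarray, blocks,
                              n_iterations: int, burn_in: int, thin: int,
                              rng: np.random.Generator,
                              target_accept: float = 0.35,
                              init_scale: float = 0.1,
                              preconditioner: np.ndarray | None = None):
    """Adaptive random-walk Metropolis-within-Gibbs on one chain.

    ``blocks`` is a sequence of index arrays. Per-block proposal scale
    follows a Robbins-Monro recursion toward ``target_accept`` and the
    proposal covariance is the running empirical covariance of the block;
    both adapt during burn-in only and are frozen afterwards.

    Returns ``(draws, acceptance_rates, logpost_trace)`` where ``draws``
    has shape ``(floor((n_iterations - burn_in) / thin), len(x0))`` and
    acceptance rates are measured on the post-burn-in iterations.
    """
    x = np.asarray(x0, dtype=float).copy()
    lp = float(logpost(x))
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-posterior")
    blocks = [np.asarray(b, dtype=np.intp) for b in blocks]
    nb = len(blocks)
    dims = [b.size for b in blocks]

    mean = [x[b].copy() for b in blocks]
    if preconditioner is None:
        log_scale = [math.log(init_scale / math.sqrt(d)) for d in dims]
        chol = [np.eye(d) for d in dims]
        m2 = [np.zeros((d, d)) for d in dims]
        n_pseudo = 0
    else:
        # start from the (e.g. Laplace) covariance estimate per block, with
        # pseudo-observations so early samples do not wash it out
        log_scale = [math.log(2.38 / math.sqrt(d)) for d in dims]
        chol = []
        m2 = []
        for b in blocks:
            cov = preconditioner[np.ix_(b, b)]
            jitter = 1e-10 + 1e-8 * np.trace(cov) / b.size
            chol.append(np.linalg.cholesky(cov + jitter * np.eye(b.size)))
            m2.append(cov.copy())
        n_pseudo = 1000
    n_adapt = 0

    n_retained = (n_iterations - burn_in) // thin
    draws = np.empty((n_retained, x.size))
    lp_trace = np.empty(n_retained)
    accepted = np.zeros(nb)
    proposed = np.zeros(nb)
    kept = 0

    for it in range(1, n_iterations + 1):
        adapting = it <= burn_in
        for k, idx in enumerate(blocks):
            d = dims[k]
            step = math.exp(log_scale[k]) * (chol[k] @ rng.standard_normal(d))
            prop = x.copy()
            prop[idx] += step
            lp_prop = float(logpost(prop))
            log_alpha = lp_prop - lp
            alpha = 1.0 if log_alpha >= 0 else math.exp(log_alpha)
            if rng.random() < alpha:
                x = prop
                lp = lp_prop
                if not adapting:
                    accepted[k] += 1
            if not adapting:
                proposed[k] += 1
            else:
                gamma = 1.0 / (1.0 + 0.1 * n_adapt) ** 0.6
                log_scale[k] += gamma * (alpha - target_accept)
        if adapting:
            n_adapt += 1
            # shrinking-weight moment estimates; pseudo-observations keep the
            # preconditioner influential until real samples accumulate
            w = 1.0 / (n_adapt + n_pseudo)
            for k, idx in enumerate(blocks):
                xb = x[idx]
                delta = xb - mean[k]
                mean[k] += w * delta
                m2[k] = (1.0 - w) * (m2[k] + w * np.outer(delta, delta))
            if n_adapt % 50 == 0:
                for k in range(nb):
                    d = dims[k]
                    if n_adapt + n_pseudo > max(4 * d, 50):
                        cov = m2[k]
                        jitter = 1e-10 + 1e-6 * np.trace(cov) / d
                        try:
                            chol[k] = np.linalg.cholesky(cov + jitter * np.eye(d))
                        except np.linalg.LinAlgError:
                            pass
        elif it > burn_in and (it - burn_in) % thin == 0:
            draws[kept] = x
            lp_trace[kept] = lp
            kept += 1

    acc = np.divide(accepted, proposed, out=np.zeros(nb), where=proposed > 0)
    return draws, acc, lp_trace


# ---------------------------------------------------------------------------
# posterior container and diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor from per-chain draws ``(C, N)``.

    Classic between/within formulation: ``sqrt(((n-1)/n * W + B/n) / W)``.
    With ``split=True`` each chain is halved first (the convention used by
    modern diagnostic libraries). Exact chain copies give
    ``sqrt((n-1)/n) <= 1``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must have shape (n_chains, n_draws)")
    if draws.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least two chains")
    if draws.shape[1] < 10:
        raise ValueError("Gelman-Rubin diagnostic needs at least 10 draws per chain")
    if split:
        half = draws.shape[1] // 2
        draws = np.vstack([draws[:, :half], draws[:, half:2 * half]])
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B_over_n = np.var(chain_means, ddof=1)
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus diagnostics and derived summaries."""

    thetas: np.ndarray                 # (n_chains, n_retained, dim)
    model: AgeAtHarvestModel
    config: MCMCConfig
    acceptance: np.ndarray             # (n_chains, n_blocks)
    block_names: tuple[str, ...]
    logpost: np.ndarray                # (n_chains, n_retained)

    REAL_PARAM_ORDER = (
        "LS_2.5", "LS_3.5", "LS_4.5", "LS_5.5+",
        "PR_2.5", "PR_3.5", "PR_4.5", "PR_5.5+",
        "SP_f", "CubSa", "CubSb", "Rep_F", "Rep_M",
        "HS_F", "HS_M", "NS", "N0_total",
    )

    @property
    def param_names(self) -> list[str]:
        return self.model.param_names

    @property
    def n_retained(self) -> int:
        return self.thetas.shape[1]

    def theta_draws(self, name: str) -> np.ndarray:
        return self.thetas[:, :, self.param_names.index(name)]

    def real_draws(self) -> dict[str, np.ndarray]:
        """Real-scale draws ``(n_chains, n_retained)`` of the headline parameters.

        ``HS_F``/``HS_M``/``NS`` are the long-term (link-mean) survival
        levels for the reference age class; year- and age-specific values
        follow from the effect draws.
        """
        t = self.thetas
        Y = self.model.Y
        out = {}
        for i, g in enumerate(("2.5", "3.5", "4.5", "5.5+")):
            out[f"LS_{g}"] = np.exp(t[:, :, i])
            out[f"PR_{g}"] = 1.0 / (1.0 + np.exp(-t[:, :, 4 + i]))
        out["SP_f"] = 1.0 / (1.0 + np.exp(-t[:, :, 8]))
        out["CubSa"] = survival_from_link(t[:, :, 9])
        out["CubSb"] = survival_from_link(t[:, :, 10])
        out["Rep_F"] = survival_from_link(t[:, :, 11])
        out["Rep_M"] = survival_from_link(t[:, :, 12])
        out["HS_F"] = survival_from_link(t[:, :, 13])
        out["HS_M"] = survival_from_link(t[:, :, 13] + t[:, :, 14])
        out["NS"] = survival_from_link(t[:, :, 16 + Y])
        out["N0_total"] = np.exp(t[:, :, 21 + 2 * Y])
        return out

    def abundance_draws(self) -> np.ndarray:
        """Total abundance per draw: shape ``(n_chains, n_retained, Y+1)``."""
        m = self.model
        C, D, _ = self.thetas.shape
        out = np.empty((C, D, m.Y + 1))
        for c in range(C):
            for i in range(D):
                N = _core._project(self.thetas[c, i], m.prop0, m.fecmap, m.Y, m.A)
                out[c, i] = np.asarray(N).sum(axis=(0, 1))
        return out

    def abundance_summary(self) -> pd.DataFrame:
        """Tidy per year/sex/age-class posterior abundance summary."""
        m = self.model
        C, D, _ = self.thetas.shape
        cells = np.empty((C * D, m.A, 2, m.Y + 1))
        k = 0
        for c in range(C):
            for i in range(D):
                cells[k] = np.asarray(
                    _core._project(self.thetas[c, i], m.prop0, m.fecmap, m.Y, m.A)
                )
                k += 1
        records = []
        from .population import SEX_LABELS, age_class_labels

        labels = age_class_labels(m.A)
        for y in range(m.Y + 1):
            for s in range(2):
                for a in range(m.A):
                    v = cells[:, a, s, y]
                    records.append({
                        "year": m.first_year + y,
                        "sex": SEX_LABELS[s],
                        "age_class": labels[a],
                        "mean": v.mean(),
                        "sd": v.std(ddof=1),
                        "cri_2.5": np.percentile(v, 2.5),
                        "cri_97.5": np.percentile(v, 97.5),
                    })
        return pd.DataFrame.from_records(records)

    def rhat(self, split: bool = False) -> pd.Series:
        """Gelman-Rubin statistic for every sampled scalar."""
        vals = {name: gelman_rubin(self.thetas[:, :, j], split=split)
                for j, name in enumerate(self.param_names)}
        return pd.Series(vals, name="rhat")

    def converged(self) -> bool:
        return bool((self.rhat() < self.config.rhat_threshold).all())

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self)

    def to_frame(self) -> pd.DataFrame:
        """Long draws table: chain, iteration, parameter, value."""
        C, D, P = self.thetas.shape
        chain = np.repeat(np.arange(C), D * P)
        iteration = np.tile(np.repeat(np.arange(D), P), C)
        parameter = np.tile(np.asarray(self.param_names), C * D)
        return pd.DataFrame({
            "chain": chain,
            "iteration": iteration,
            "parameter": parameter,
            "value": self.thetas.reshape(-1),
        })

    def to_inference_data(self):
        """ArviZ ``InferenceData`` with real-scale headline parameters."""
        import arviz as az

        data = {k: v for k, v in self.real_draws().items()}
        data["N_total"] = self.abundance_draws()
        return az.from_dict(posterior=data)


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Mean, sd and central 95% credible interval per headline parameter
    and per-year total abundance (percentile rule: linear interpolation)."""
    rows = {}
    real = samples.real_draws()
    for name in samples.REAL_PARAM_ORDER:
        rows[name] = real[name].reshape(-1)
    totals = samples.abundance_draws()
    for y in range(totals.shape[2]):
        rows[f"N_total_{samples.model.first_year + y}"] = totals[:, :, y].reshape(-1)
    records = []
    for name, v in rows.items():
        records.append({
            "parameter": name,
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "cri_2.5": float(np.percentile(v, 2.5)),
            "cri_97.5": float(np.percentile(v, 97.5)),
        })
    return pd.DataFrame.from_records(records).set_index("parameter")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(data: HarvestData, priors: DemographicPriors,
             config: MCMCConfig | None = None) -> PosteriorSamples:
    """Fit the state-space model; deterministic given ``config.seed``."""
    config = config or MCMCConfig()
    model = AgeAtHarvestModel(data, priors)
    block_names, block_idx = zip(*model.blocks())
    map_theta, preconditioner = model.laplace_approximation()
    chol_full = np.linalg.cholesky(
        preconditioner + 1e-10 * np.eye(model.dim)
    )
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    all_draws = np.empty((config.n_chains, config.n_retained, model.dim))
    all_lp = np.empty((config.n_chains, config.n_retained))
    acc = np.empty((config.n_chains, len(block_idx)))
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = None
        for _ in range(config.max_init_retries):
            # over-dispersed around the mode: 3x the Laplace spread
            cand = map_theta + 3.0 * (chol_full @ rng.standard_normal(model.dim))
            if np.isfinite(model.log_posterior(cand)):
                theta0 = cand
                break
        if theta0 is None:
            raise RuntimeError(
                "could not initialize chain: log-posterior non-finite at every "
                f"prior draw (first data year {int(data.years[0])})"
            )
        draws, a, lp = adaptive_block_metropolis(
            model.log_posterior, theta0, block_idx,
            config.n_iterations, config.burn_in, config.thin, rng,
            target_accept=config.target_accept, init_scale=config.init_scale,
            preconditioner=preconditioner,
        )
        all_draws[c] = draws
        all_lp[c] = lp
        acc[c] = a
    return PosteriorSamples(thetas=all_draws, model=model, config=config,
                            acceptance=acc, block_names=tuple(block_names),
                            logpost=all_lp)
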