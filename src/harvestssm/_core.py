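"""Numerical core of the state-space model, JIT-compiled when numba is present.

The sampled parameter vector ``theta`` (all entries unconstrained) is laid
out as, with ``Y`` data years:

====================  =========================================
index                 parameter
====================  =========================================
0:4                   log litter size, 4 fecundity groups
4:8                   logit pregnancy rate, 4 groups
8                     logit female newborn proportion
9                     link-scale cub survival A
10                    link-scale cub survival B
11, 12                link-scale reporting rate (F, M)
13                    link-scale female harvest-survival long-term mean
14                    link-scale male - female harvest-survival contrast
15:15+Y               link-scale female harvest-survival year levels
15+Y                  log annual precision of HS year levels
16+Y                  link-scale non-harvest survival mean
17+Y:17+2Y            link-scale non-harvest survival year levels
17+2Y                 log annual precision of NS year levels
18+2Y:21+2Y           age-class offsets (classes 0..2; 3+ is reference)
21+2Y                 log initial total abundance
====================  =========================================

Year variation is parameterized in *centered* form: the sampled year
values are absolute link-scale levels with a normal prior around the
corresponding long-term mean (female level for harvest survival; the
male level adds the sex contrast ``mu_M - mu_F``). With informative
yearly harvest data this mixes far better than sampling offsets around
the mean, and it is an invertible linear map of the same model.

The survival link is ``s = exp(-exp(eta))`` (complementary log-log on
mortality). Hyperparameters are packed into a flat float vector ``hp``
(see :data:`HP_SIZE` and the pack function in :mod:`harvestssm.inference`).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# hp vector layout
HP_LS_SHAPE = 0      # 4 entries
HP_LS_RATE = 4       # 4 entries
HP_PR_ALPHA = 8      # 4 entries
HP_PR_BETA = 12      # 4 entries
HP_SP_ALPHA = 16
HP_SP_BETA = 17
HP_CUBSA = 18        # link mean, precision
HP_CUBSB = 20
HP_REP = 22
HP_HSF = 24
HP_HSM = 26
HP_NS = 28
HP_ANNPREC = 30      # shape, rate of the annual-precision gamma hyperprior
HP_LHR_SD = 32
HP_LOGN0_MEAN = 33
HP_LOGN0_SD = 34
HP_SIZE = 35

N_LHR = 3


def theta_dim(n_years: int) -> int:
    return 22 + 2 * n_years


@njit(cache=True)
def _gamma_logpdf(x, shape, rate):
    return shape * math.log(rate) - math.lgamma(shape) + (shape - 1.0) * math.log(x) - rate * x


@njit(cache=True)
def _beta_logpdf(x, a, b):
    return (math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
            + (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x))


@njit(cache=True)
def _norm_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.9189385332046727


@njit(cache=True)
def _unpack_rates(theta, Y, A):
    """Real-scale rates from theta: (LS, PR, spf, cubsa, cubsb, rep, HS, NS)."""
    LS = np.empty(4)
    PR = np.empty(4)
    for i in range(4):
        LS[i] = math.exp(theta[i])
        PR[i] = 1.0 / (1.0 + math.exp(-theta[4 + i]))
    spf = 1.0 / (1.0 + math.exp(-theta[8]))
    cubsa = math.exp(-math.exp(theta[9]))
    cubsb = math.exp(-math.exp(theta[10]))
    rep = np.empty(2)
    rep[0] = math.exp(-math.exp(theta[11]))
    rep[1] = math.exp(-math.exp(theta[12]))

    HS = np.empty((A, 2, Y))
    sex_contrast = theta[14]
    for y in range(Y):
        level = theta[15 + y]
        for s in range(2):
            delta = 0.0 if s == 0 else sex_contrast
            for a in range(A):
                off = theta[18 + 2 * Y + a] if a < N_LHR else 0.0
                HS[a, s, y] = math.exp(-math.exp(level + delta + off))
    NS = np.empty(Y)
    for y in range(Y):
        NS[y] = math.exp(-math.exp(theta[17 + Y + y]))
    return LS, PR, spf, cubsa, cubsb, rep, HS, NS


@njit(cache=True)
def _project(theta, prop0, fecmap, Y, A):
    """Abundance (A, 2, Y+1) implied by theta: deterministic projection."""
    LS, PR, spf, cubsa, cubsb, rep, HS, NS = _unpack_rates(theta, Y, A)
    n0 = math.exp(theta[21 + 2 * Y])

    fec = np.zeros(A)
    for a in range(A):
        g = fecmap[a]
        if g >= 0:
            fec[a] = LS[g] * PR[g]
    cub = cubsa * cubsb
    sp = np.empty(2)
    sp[0] = spf
    sp[1] = 1.0 - spf

    N = np.zeros((A, 2, Y + 1))
    for a in range(A):
        for s in range(2):
            N[a, s, 0] = n0 * prop0[a, s]
    for y in range(1, Y + 1):
        lag = y - 2 if y >= 2 else 0
        recruits = 0.0
        for a in range(A):
            recruits += N[a, 0, lag] * fec[a]
        recruits *= cub
        for s in range(2):
            N[0, s, y] = sp[s] * recruits
            for a in range(1, A - 1):
                N[a, s, y] = N[a - 1, s, y - 1] * HS[a - 1, s, y - 1] * NS[y - 1]
            N[A - 1, s, y] = (N[A - 2, s, y - 1] * HS[A - 2, s, y - 1]
                              + N[A - 1, s, y - 1] * HS[A - 1, s, y - 1]) * NS[y - 1]
    return N


@njit(cache=True)
def _log_prior(theta, hp, Y):
    lp = 0.0
    # litter sizes: gamma priors on the real scale, log transform Jacobian
    for i in range(4):
        ls = math.exp(theta[i])
        lp += _gamma_logpdf(ls, hp[HP_LS_SHAPE + i], hp[HP_LS_RATE + i]) + theta[i]
    # pregnancy rates and sex proportion: beta priors, logit Jacobian
    for i in range(4):
        p = 1.0 / (1.0 + math.exp(-theta[4 + i]))
        lp += _beta_logpdf(p, hp[HP_PR_ALPHA + i], hp[HP_PR_BETA + i]) + math.log(p * (1.0 - p))
    p = 1.0 / (1.0 + math.exp(-theta[8]))
    lp += _beta_logpdf(p, hp[HP_SP_ALPHA], hp[HP_SP_BETA]) + math.log(p * (1.0 - p))
    # link-scale normals (no Jacobian: sampled on the link scale)
    lp += _norm_logpdf(theta[9], hp[HP_CUBSA], 1.0 / math.sqrt(hp[HP_CUBSA + 1]))
    lp += _norm_logpdf(theta[10], hp[HP_CUBSB], 1.0 / math.sqrt(hp[HP_CUBSB + 1]))
    rep_sd = 1.0 / math.sqrt(hp[HP_REP + 1])
    lp += _norm_logpdf(theta[11], hp[HP_REP], rep_sd)
    lp += _norm_logpdf(theta[12], hp[HP_REP], rep_sd)
    lp += _norm_logpdf(theta[13], hp[HP_HSF], 1.0 / math.sqrt(hp[HP_HSF + 1]))
    # the male long-term mean is mu_F + contrast; its prior lands on the sum
    lp += _norm_logpdf(theta[13] + theta[14], hp[HP_HSM], 1.0 / math.sqrt(hp[HP_HSM + 1]))
    lp += _norm_logpdf(theta[16 + Y], hp[HP_NS], 1.0 / math.sqrt(hp[HP_NS + 1]))
    # year levels around their long-term means, gamma hyperpriors on precisions
    tau_hs = math.exp(theta[15 + Y])
    lp += _gamma_logpdf(tau_hs, hp[HP_ANNPREC], hp[HP_ANNPREC + 1]) + theta[15 + Y]
    sd_hs = 1.0 / math.sqrt(tau_hs)
    for y in range(Y):
        lp += _norm_logpdf(theta[15 + y], theta[13], sd_hs)
    tau_ns = math.exp(theta[17 + 2 * Y])
    lp += _gamma_logpdf(tau_ns, hp[HP_ANNPREC], hp[HP_ANNPREC + 1]) + theta[17 + 2 * Y]
    sd_ns = 1.0 / math.sqrt(tau_ns)
    for y in range(Y):
        lp += _norm_logpdf(theta[17 + Y + y], theta[16 + Y], sd_ns)
    # age offsets and initial total
    for k in range(N_LHR):
        lp += _norm_logpdf(theta[18 + 2 * Y + k], 0.0, hp[HP_LHR_SD])
    lp += _norm_logpdf(theta[21 + 2 * Y], hp[HP_LOGN0_MEAN], hp[HP_LOGN0_SD])
    return lp


@njit(cache=True)
def _log_lik(theta, O, C, lgam_C, prop0, fecmap, Y, A):
    LS, PR, spf, cubsa, cubsb, rep, HS, NS = _unpack_rates(theta, Y, A)
    N = _project(theta, prop0, fecmap, Y, A)
    lp = 0.0
    for y in range(Y):
        total = 0.0
        n_aged = 0.0
        logp_sum = 0.0
        for a in range(A):
            for s in range(2):
                h = N[a, s, y] * (1.0 - HS[a, s, y]) * rep[s]
                total += h
        if total <= 0.0:
            if O[y] > 0.0:
                return -np.inf
            continue
        for a in range(A):
            for s in range(2):
                c = C[a, s, y]
                n_aged += c
                if c > 0.0:
                    h = N[a, s, y] * (1.0 - HS[a, s, y]) * rep[s]
                    if h <= 0.0:
                        return -np.inf
                    logp_sum += c * math.log(h / total)
        # Poisson total + multinomial aged/sexed counts
        lp += O[y] * math.log(total) - total - math.lgamma(O[y] + 1.0)
        lp += math.lgamma(n_aged + 1.0) - lgam_C[y] + logp_sum
    return lp


@njit(cache=True)
def _log_post(theta, O, C, lgam_C, prop0, fecmap, hp, Y, A):
    lp = _log_prior(theta, hp, Y)
    if not np.isfinite(lp):
        return -np.inf
    lp += _log_lik(theta, O, C, lgam_C, prop0, fecmap, Y, A)
    if not np.isfinite(lp):
        return -np.inf
    return lp
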