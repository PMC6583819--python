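"""Empirical-Bayes Poisson-gamma model with censored-count augmentation.

Each cell count is Poisson, y_ik ~ Pois(n_ik * lambda_ik), with a conjugate
gamma prior lambda_ik ~ Gamma(y0 + offset, n0) whose parameters read as a
prior number of events (y0) and a prior population size (n0).  The prior is
calibrated empirically: y0/n0 equals the state-wide average rate, the n0
follow a reference age distribution, and the total prior events per state
is fixed (default 6) so the prior stays weakly informative.  The small
shape offset (default 1/3) guards against degenerate posteriors in age
groups dominated by zero counts.

With suppression, the unknown counts are latent: a Gibbs sampler alternates
conjugate gamma draws of every lambda_ik with truncated-Poisson draws of the
suppressed counts over the censoring set.  Without suppression the sampler
reduces to independent draws from the closed-form posterior
Gamma(y + y0 + offset, n + n0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import MCMCConfig
from .data import CensoredCountTable
from .substitution import StateRateTable
from .summaries import PosteriorDraws

logger = logging.getLogger(__name__)

DEFAULT_OFFSET = 1.0 / 3.0
DEFAULT_TOTAL_PRIOR_EVENTS = 6.0


@dataclass(frozen=True)
class PriorTable:
    """Per-(state, age) prior events y0 and prior populations n0.

    Within each state, sum_k y0_k equals ``total_prior_events`` and the n0_k
    are proportional to the reference age distribution.
    """

    y0: dict[tuple[str, str], float]
    n0: dict[tuple[str, str], float]
    offset: float = DEFAULT_OFFSET
    total_prior_events: float = DEFAULT_TOTAL_PRIOR_EVENTS

    def arrays(self, censored: CensoredCountTable) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast the (state, age) prior onto the table's I x K grid."""
        I, K = censored.I, censored.K
        y0 = np.empty((I, K))
        n0 = np.empty((I, K))
        for i, a in enumerate(censored.area_ids):
            s = censored.state_of[a]
            for k, g in enumerate(censored.ages):
                y0[i, k] = self.y0[(s, g)]
                n0[i, k] = self.n0[(s, g)]
        return y0, n0


def build_prior(
    rates: StateRateTable,
    age_distribution,
    ages: tuple[str, ...] | None = None,
    total_prior_events: float = DEFAULT_TOTAL_PRIOR_EVENTS,
    offset: float = DEFAULT_OFFSET,
) -> PriorTable:
    """Calibrate the gamma prior from state rates and an age distribution.

    Solves, per state, for the scale c such that n0_k = c * p_k and
    y0_k = rate_sk * n0_k sum to ``total_prior_events``:
    c = total / sum_k rate_sk p_k.  A zero state rate contributes no prior
    events for that age; a state whose rates vanish in every age group has
    no solution and is an error.
    """
    p = np.asarray(age_distribution, dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("age distribution must be nonnegative with positive sum")
    p = p / p.sum()
    states = sorted({s for s, _ in rates.rate})
    if ages is None:
        ages = tuple(sorted({g for _, g in rates.rate}))
    if len(ages) != len(p):
        raise ValueError("age distribution length does not match age groups")
    y0: dict[tuple[str, str], float] = {}
    n0: dict[tuple[str, str], float] = {}
    for s in states:
        lam = np.array([rates.rate[(s, g)] for g in ages])
        denom = float(lam @ p)
        if denom <= 0:
            raise ValueError(f"prior undefined for state {s!r}: all rates zero")
        c = total_prior_events / denom
        for k, g in enumerate(ages):
            n0[(s, g)] = c * p[k]
            y0[(s, g)] = lam[k] * c * p[k]
    return PriorTable(y0, n0, offset=offset, total_prior_events=total_prior_events)


def posterior_params(
    y: float, n: float, y0: float, n0: float, offset: float = DEFAULT_OFFSET
) -> tuple[float, float]:
    """Conjugate posterior Gamma(shape, rate) for one uncensored cell.

    shape = y + y0 + offset, rate = n + n0; the posterior mean shape/rate is
    a precision-weighted compromise between the prior rate y0/n0 and the
    data rate y/n (the exact average when offset = 0 and n = n0).
    """
    if min(y, n, y0, n0) < 0 or offset < 0:
        raise ValueError("all inputs must be nonnegative")
    return (y + y0 + offset, n + n0)


def truncated_poisson_pmf(mean: float, support) -> np.ndarray:
    """Exact pmf of a Poisson(mean) truncated to an integer support set."""
    support = np.asarray(support, dtype=np.int64)
    if support.size == 0:
        raise ValueError("support must be nonempty")
    if mean < 0:
        raise ValueError("mean must be >= 0")
    if mean == 0:
        if 0 not in support:
            raise ValueError("Poisson(0) has no mass on the support")
        return (support == 0).astype(float)
    logw = support * np.log(mean) - mean - gammaln(support + 1.0)
    return np.exp(logw - logsumexp(logw))


def sample_truncated_poisson(mean: float, support, rng: np.random.Generator) -> int:
    """Draw one count from a Poisson(mean) restricted to ``support``.

    Exact normalized enumeration in log space (support has at most
    ``threshold`` values), so the cost is deterministic and the
    distribution exact even for very large means.
    """
    support = np.asarray(support, dtype=np.int64)
    pmf = truncated_poisson_pmf(mean, support)
    return int(rng.choice(support, p=pmf))


def _sample_truncated_poisson_many(
    means: np.ndarray, support: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized truncated-Poisson draws, one per mean."""
    means = np.asarray(means, dtype=float)
    logw = (
        support[:, None] * np.log(np.maximum(means, 1e-300))[None, :]
        - means[None, :]
        - gammaln(support + 1.0)[:, None]
    )
    if 0 in support and np.any(means == 0):
        logw[:, means == 0] = -np.inf
        logw[np.ix_(support == 0, means == 0)] = 0.0
    logw -= logsumexp(logw, axis=0, keepdims=True)
    cum = np.cumsum(np.exp(logw), axis=0)
    u = rng.random(means.shape[0])
    idx = (cum < u[None, :]).sum(axis=0)
    return support[np.minimum(idx, support.size - 1)]


def fit_poisson_gamma(
    censored: CensoredCountTable,
    prior: PriorTable,
    mcmc: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Gibbs sampler for the Poisson-gamma model under left-censoring.

    Alternates (a) lambda_ik ~ Gamma(y_ik + y0 + offset, n_ik + n0) for every
    cell, using the current imputed count in suppressed cells, and
    (b) y_ik ~ truncated Poisson(n_ik lambda_ik) over the censoring set for
    suppressed cells.  Suppressed counts are initialized at the midpoint of
    the censoring set.  Reproducible given ``mcmc.seed``.
    """
    mcmc = mcmc or MCMCConfig()
    y0, n0 = prior.arrays(censored)
    I, K = censored.I, censored.K
    mask = censored.suppressed
    cells = tuple((int(i), int(k)) for i, k in zip(*np.nonzero(mask)))
    support = censored.censor_set()
    n = censored.n.astype(float)
    shape_base = censored.observed.astype(float).copy()
    shape_base[mask] = 0.0
    rate = n + n0

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    lam_chains, imp_chains = [], []
    if cells and support.size == 0:
        raise ValueError("suppressed cells present but the censoring set is empty")
    init_count = int(support[support.size // 2]) if support.size else 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        imputed = np.full(len(cells), init_count, dtype=np.int64)
        lam_out = np.empty((mcmc.draws, I, K))
        imp_out = np.empty((mcmc.draws, len(cells)), dtype=np.int64)
        ycur = shape_base.copy()
        rows = np.array([c[0] for c in cells], dtype=np.int64)
        cols = np.array([c[1] for c in cells], dtype=np.int64)
        if len(cells):
            ycur[rows, cols] = imputed
        stored = 0
        total_iter = mcmc.burnin + mcmc.draws * mcmc.thin
        for it in range(total_iter):
            lam = rng.gamma(shape=ycur + y0 + prior.offset, scale=1.0 / rate)
            if len(cells):
                mu = n[rows, cols] * lam[rows, cols]
                imputed = _sample_truncated_poisson_many(mu, support, rng)
                ycur[rows, cols] = imputed
            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
                lam_out[stored] = lam
                imp_out[stored] = imputed
                stored += 1
        lam_chains.append(lam_out)
        imp_chains.append(imp_out)

    lam_all = np.concatenate(lam_chains, axis=0)
    imp_all = np.concatenate(imp_chains, axis=0)
    _warn_if_unconverged(lam_chains, mcmc)
    return PosteriorDraws(
        lam=lam_all,
        imputed=imp_all,
        suppressed_cells=cells,
        area_ids=censored.area_ids,
        ages=censored.ages,
        model_tag="poisson_gamma",
    )


def _warn_if_unconverged(
    lam_chains: list[np.ndarray], mcmc: MCMCConfig, n_cells: int = 50
) -> None:
    """Log a Gelman-Rubin warning on a random cell subset (never an error)."""
    if len(lam_chains) < 2:
        return
    try:
        import arviz as az
    except Exception:  # pragma: no cover
        return
    L, I, K = lam_chains[0].shape
    rng = np.random.default_rng(mcmc.seed)
    flat = rng.choice(I * K, size=min(n_cells, I * K), replace=False)
    stacked = np.stack([c.reshape(L, I * K)[:, flat] for c in lam_chains])
    rhat = az.rhat(az.convert_to_dataset(stacked))["x"].to_numpy()
    worst = float(np.nanmax(rhat))
    if worst > 1.05:
        logger.warning("Gelman-Rubin R-hat %.3f > 1.05 on sampled cells", worst)
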