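"""Poisson log-linear model with multivariate CAR (MCAR) spatial effects.

The log rate of each cell decomposes as

    log lambda_ik = beta_0k + x_ik' beta_k + z_ik + phi_ik,

where z_ik is a spatial effect shrunk toward the neighboring areas' values
and phi_ik an exchangeable (nonspatial) effect.  The K spatial fields are
coupled through a proper multivariate CAR prior (Gelfand-Vounatsou form):
the precision of vec(z) is Lambda (x) M(alpha) with M(alpha) = D_w - alpha W,
a single spatial-autocorrelation parameter alpha in [0, 1) shared across age
groups, and a K x K between-age precision Lambda.  This is the simplest
multivariate extension of the CAR model that lets correlated age groups
borrow strength from one another.

Inference is by MCMC with data augmentation: suppressed counts are latent
and drawn from their exact truncated-Poisson full conditionals each sweep.
Gaussian field updates use adaptive random-walk Metropolis over graph-color
blocks (cells of one color at one age are conditionally independent, so the
block update is a valid collection of single-site moves); Lambda and the
exchangeable variances have conjugate Wishart / inverse-gamma full
conditionals; alpha moves on the logit scale.  The spatial field is
re-centered to mean zero per age each sweep, with the offset absorbed into
the intercept, to break the intercept/field confounding.

The hyperprior defaults below (wide normal intercepts, Wishart(K+1, I) for
Lambda, InverseGamma(0.5, 0.0005) for the exchangeable variances in the
convolution-prior tradition, uniform alpha) are this package's own
weakly-informative choices; all are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.special import expit, gammaln, logit
from scipy.stats import invgamma, norm, wishart

from .config import MCMCConfig
from .data import AdjacencyGraph, CensoredCountTable
from .poisson_gamma import _sample_truncated_poisson_many
from .summaries import PosteriorDraws

logger = logging.getLogger(__name__)


@dataclass
class MCARHyper:
    """Hyperparameters of the MCAR hierarchy (all priors are proper)."""

    beta0_sd: float = 100.0
    wishart_df: float | None = None  # default K + 1, set at fit time
    wishart_scale: np.ndarray | None = None  # default identity
    sigma2_shape: float = 0.5
    sigma2_rate: float = 0.0005
    iso_var: float = 100.0  # variance of z for areas with no neighbors
    fix_alpha: float | None = None  # fix alpha instead of sampling it


@dataclass
class MCARState:
    """One MCMC state of the model."""

    beta0: np.ndarray  # (K,)
    z: np.ndarray  # (I, K)
    phi: np.ndarray  # (I, K)
    Lambda: np.ndarray  # (K, K) precision, symmetric PD
    alpha: float
    sigma2: np.ndarray  # (K,)
    imputed: np.ndarray  # counts for suppressed cells, row-major cell order
    beta: np.ndarray | None = None  # (p, K) covariate coefficients
    x: np.ndarray | None = None  # (I, p) covariates

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1):
            raise ValueError("alpha must lie in [0, 1)")
        L = np.asarray(self.Lambda, float)
        if not np.allclose(L, L.T):
            raise ValueError("Lambda must be symmetric")
        np.linalg.cholesky(L)  # raises if not positive definite
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be positive")

    def log_lambda(self) -> np.ndarray:
        eta = self.beta0[None, :] + self.z + self.phi
        if self.beta is not None and self.x is not None:
            eta = eta + self.x @ self.beta
        return eta


def car_precision(graph: AdjacencyGraph, alpha: float, order=None):
    """Proper-CAR precision M(alpha) = D_w - alpha * W (sparse, symmetric).

    Positive definite on the non-isolated areas for any 0 <= alpha < 1;
    rows of isolated areas are identically zero and are handled by an
    independent Gaussian prior in the model.
    """
    if not (0 <= alpha < 1):
        raise ValueError("alpha must lie in [0, 1)")
    order = tuple(order) if order is not None else graph.areas
    W = graph.adjacency_matrix(order)
    d = np.asarray(W.sum(axis=1)).ravel()
    return sparse.diags(d) - alpha * W


def _graph_colors(graph: AdjacencyGraph, order: tuple[str, ...]) -> list[np.ndarray]:
    """Greedy proper coloring -> index blocks of mutually non-adjacent areas."""
    g = nx.Graph()
    g.add_nodes_from(order)
    for a in order:
        g.add_edges_from((a, b) for b in graph.neighbors.get(a, frozenset()))
    coloring = nx.greedy_color(g, strategy="largest_first")
    idx = {a: i for i, a in enumerate(order)}
    ncol = max(coloring.values()) + 1 if coloring else 1
    blocks = [[] for _ in range(ncol)]
    for a, c in coloring.items():
        blocks[c].append(idx[a])
    return [np.array(sorted(b), dtype=np.int64) for b in blocks if b]


def log_posterior(
    state: MCARState,
    censored: CensoredCountTable,
    graph: AdjacencyGraph,
    hyper: MCARHyper | None = None,
) -> float:
    """Joint log posterior density (up to the model's fixed constants).

    Includes the Poisson likelihood at observed + imputed counts, the MCAR
    prior on z (with its alpha- and Lambda-dependent normalizing constant),
    the exchangeable-effect and hyper priors.  Raises if any component is
    non-finite, naming the component.
    """
    hyper = hyper or MCARHyper()
    I, K = censored.I, censored.K
    y = censored.observed.astype(float).copy()
    rows, cols = np.nonzero(censored.suppressed)
    y[rows, cols] = state.imputed
    eta = state.log_lambda() + np.log(censored.n)
    parts: dict[str, float] = {}
    parts["likelihood"] = float(
        np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0))
    )

    M = car_precision(graph, state.alpha, order=censored.area_ids).toarray()
    deg = np.asarray(
        graph.adjacency_matrix(censored.area_ids).sum(axis=1)
    ).ravel()
    noniso = deg > 0
    I_ne = int(noniso.sum())
    Z = state.z
    if I_ne:
        Mnn = M[np.ix_(noniso, noniso)]
        sign, logdet_M = np.linalg.slogdet(Mnn)
        _, logdet_L = np.linalg.slogdet(state.Lambda)
        quad = float(np.trace(state.Lambda @ Z[noniso].T @ Mnn @ Z[noniso]))
        parts["mcar_prior"] = (
            0.5 * K * logdet_M
            + 0.5 * I_ne * logdet_L
            - 0.5 * quad
            - 0.5 * I_ne * K * np.log(2 * np.pi)
        )
    else:
        parts["mcar_prior"] = 0.0
    if (~noniso).any():
        parts["isolated_z_prior"] = float(
            norm.logpdf(Z[~noniso], 0.0, np.sqrt(hyper.iso_var)).sum()
        )
    parts["phi_prior"] = float(
        sum(
            norm.logpdf(state.phi[:, k], 0.0, np.sqrt(state.sigma2[k])).sum()
            for k in range(K)
        )
    )
    parts["beta0_prior"] = float(norm.logpdf(state.beta0, 0.0, hyper.beta0_sd).sum())
    df = hyper.wishart_df if hyper.wishart_df is not None else K + 1
    scale = hyper.wishart_scale if hyper.wishart_scale is not None else np.eye(K)
    parts["lambda_prior"] = float(wishart.logpdf(state.Lambda, df, scale))
    parts["sigma2_prior"] = float(
        invgamma.logpdf(state.sigma2, hyper.sigma2_shape, scale=hyper.sigma2_rate).sum()
    )
    parts["alpha_prior"] = 0.0  # uniform on [0, 1)
    for name, v in parts.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite log-posterior component: {name}")
    return float(sum(parts.values()))


def _sym_inv(A: np.ndarray) -> np.ndarray:
    out = np.linalg.inv(A)
    return 0.5 * (out + out.T)


class _StepAdapter:
    """Robbins-Monro tuning of a log step size toward a target acceptance."""

    def __init__(self, init_step: float, target: float):
        self.log_step = np.log(init_step)
        self.target = target

    def step(self) -> float:
        return float(np.exp(self.log_step))

    def update(self, acc_rate: float, t: int) -> None:
        self.log_step += (acc_rate - self.target) / (t + 1) ** 0.6


def fit_mcar(
    censored: CensoredCountTable,
    graph: AdjacencyGraph,
    covariates: np.ndarray | None = None,
    mcmc: MCMCConfig | None = None,
    hyper: MCARHyper | None = None,
) -> PosteriorDraws:
    """MCMC for the Poisson-MCAR model under left-censoring.

    Per sweep: (a) impute suppressed counts from exact truncated-Poisson
    conditionals; (b) Metropolis updates of the intercepts, of z over
    graph-color blocks per age, and of phi cell-wise; (c) conjugate Wishart
    draw of Lambda and inverse-gamma draws of the exchangeable variances;
    (d) logit-scale Metropolis on alpha using precomputed eigenvalues for
    the determinant term; (e) per-age re-centering of z absorbed into the
    intercepts.  Reproducible given ``mcmc.seed``.
    """
    mcmc = mcmc or MCMCConfig()
    hyper = hyper or MCARHyper()
    if tuple(graph.areas) != tuple(censored.area_ids):
        missing = set(censored.area_ids) ^ set(graph.areas)
        if missing:
            raise ValueError(f"graph/table area mismatch: {sorted(missing)[:5]}")
    I, K = censored.I, censored.K
    order = censored.area_ids
    W = graph.adjacency_matrix(order).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    noniso = d > 0
    I_ne = int(noniso.sum())
    colors = _graph_colors(graph, order)
    W_by_color = [W[S] for S in colors]
    iso_by_color = [~noniso[S] for S in colors]

    # eigenvalues of D^{-1/2} W D^{-1/2} on the non-isolated block drive
    # log|M(alpha)| = const + sum log(1 - alpha * omega)
    if I_ne:
        Wnn = W[np.ix_(noniso, noniso)].toarray()
        dn = d[noniso]
        B = Wnn / np.sqrt(np.outer(dn, dn))
        omega = eigh(B, eigvals_only=True)
    else:
        omega = np.zeros(0)

    mask = censored.suppressed
    cells = tuple((int(i), int(k)) for i, k in zip(*np.nonzero(mask)))
    rows = np.array([c[0] for c in cells], dtype=np.int64)
    kols = np.array([c[1] for c in cells], dtype=np.int64)
    support = censored.censor_set()
    n = censored.n.astype(float)
    logn = np.log(n)

    X = covariates
    p = 0 if X is None else X.shape[1]

    df0 = hyper.wishart_df if hyper.wishart_df is not None else K + 1
    V0 = hyper.wishart_scale if hyper.wishart_scale is not None else np.eye(K)
    V0inv = np.linalg.inv(V0)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    lam_chains, imp_chains = [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        ycur = censored.observed.astype(float).copy()
        init_count = int(support[support.size // 2]) if support.size else 0
        imputed = np.full(len(cells), init_count, dtype=np.int64)
        if len(cells):
            ycur[rows, kols] = imputed
        beta0 = np.log((ycur.sum(axis=0) + 0.5) / n.sum(axis=0))
        B_cov = np.zeros((p, K)) if p else None
        z = np.zeros((I, K))
        phi = np.zeros((I, K))
        Lam = np.eye(K)
        sigma2 = np.full(K, 0.01)
        alpha = hyper.fix_alpha if hyper.fix_alpha is not None else 0.5

        ad_z = [_StepAdapter(mcmc.init_step, mcmc.target_accept) for _ in range(K)]
        ad_phi = [_StepAdapter(mcmc.init_step, mcmc.target_accept) for _ in range(K)]
        ad_b = [_StepAdapter(0.1, mcmc.target_accept) for _ in range(K)]
        ad_a = _StepAdapter(0.5, mcmc.target_accept)
        ad_bc = [_StepAdapter(0.1, mcmc.target_accept) for _ in range(K)] if p else []

        lam_out = np.empty((mcmc.draws, I, K))
        imp_out = np.empty((mcmc.draws, len(cells)), dtype=np.int64)
        stored = 0
        total_iter = mcmc.burnin + mcmc.draws * mcmc.thin
        eta = beta0[None, :] + z + phi
        if p:
            eta = eta + X @ B_cov
        for it in range(total_iter):
            adapting = mcmc.adapt and it < mcmc.burnin

            # intercepts, one Metropolis move per age group
            for k in range(K):
                step = ad_b[k].step()
                delta = step * rng.standard_normal()
                lam_col = np.exp(eta[:, k])
                dloglik = delta * ycur[:, k].sum() - np.sum(
                    n[:, k] * lam_col * (np.exp(delta) - 1.0)
                )
                dlogprior = (
                    -((beta0[k] + delta) ** 2 - beta0[k] ** 2)
                    / (2 * hyper.beta0_sd**2)
                )
                acc = np.log(rng.random()) < dloglik + dlogprior
                if acc:
                    beta0[k] += delta
                    eta[:, k] += delta
                if adapting:
                    ad_b[k].update(float(acc), it)

            # covariate coefficients (off unless covariates supplied)
            for k in range(K) if p else []:
                step = ad_bc[k].step()
                delta = step * rng.standard_normal(p)
                deta = X @ delta
                lam_col = np.exp(eta[:, k])
                dloglik = float(
                    np.sum(ycur[:, k] * deta - n[:, k] * lam_col * (np.exp(deta) - 1.0))
                )
                bk = B_cov[:, k]
                dlogprior = float(
                    -np.sum((bk + delta) ** 2 - bk**2) / (2 * hyper.beta0_sd**2)
                )
                acc = np.log(rng.random()) < dloglik + dlogprior
                if acc:
                    B_cov[:, k] += delta
                    eta[:, k] += deta
                if adapting:
                    ad_bc[k].update(float(acc), it)

            # spatial field z: color blocks are conditionally independent
            for k in range(K):
                step = ad_z[k].step()
                Lkk = Lam[k, k]
                c_vec = z @ Lam[:, k] - Lkk * z[:, k]
                acc_sum, acc_n = 0.0, 0
                for S, W_S, iso_S in zip(colors, W_by_color, iso_by_color):
                    u = z[S, k]
                    prop = u + step * rng.standard_normal(S.size)
                    eta_S = eta[S, k]
                    lam_S = np.exp(eta_S)
                    deta = prop - u
                    dloglik = ycur[S, k] * deta - n[S, k] * lam_S * (
                        np.exp(deta) - 1.0
                    )
                    nbr = W_S @ z[:, k]
                    b = d[S] * c_vec[S] - alpha * (W_S @ c_vec)
                    r = -alpha * Lkk * nbr + b
                    dQ = 0.5 * Lkk * d[S] * (prop**2 - u**2) + deta * r
                    dlogprior = -dQ
                    if iso_S.any():
                        dlogprior = dlogprior - np.where(
                            iso_S, (prop**2 - u**2) / (2 * hyper.iso_var), 0.0
                        )
                    acc = np.log(rng.random(S.size)) < dloglik + dlogprior
                    z[S[acc], k] = prop[acc]
                    eta[S[acc], k] += deta[acc]
                    acc_sum += acc.sum()
                    acc_n += S.size
                if adapting:
                    ad_z[k].update(acc_sum / max(acc_n, 1), it)

            # re-center z per age; absorb the shift into the intercept
            shift = z.mean(axis=0)
            z -= shift[None, :]
            beta0 += shift

            # exchangeable effects phi, cell-wise
            for k in range(K):
                step = ad_phi[k].step()
                u = phi[:, k]
                prop = u + step * rng.standard_normal(I)
                deta = prop - u
                lam_col = np.exp(eta[:, k])
                dloglik = ycur[:, k] * deta - n[:, k] * lam_col * (np.exp(deta) - 1.0)
                dlogprior = -(prop**2 - u**2) / (2 * sigma2[k])
                acc = np.log(rng.random(I)) < dloglik + dlogprior
                phi[acc, k] = prop[acc]
                eta[acc, k] += deta[acc]
                if adapting:
                    ad_phi[k].update(float(acc.mean()), it)

            # conjugate draws: Lambda | z, sigma2 | phi
            if I_ne:
                Dz = z * d[:, None]
                S_z = Dz.T @ z - alpha * (z.T @ (W @ z))
                scale_post = _sym_inv(V0inv + S_z)
                try:
                    Lam = wishart.rvs(df0 + I_ne, scale_post, random_state=rng)
                except np.linalg.LinAlgError:  # keep current Lambda
                    pass
                Lam = np.atleast_2d(Lam)
            else:
                Lam = np.atleast_2d(wishart.rvs(df0, V0, random_state=rng))
            sigma2 = 1.0 / rng.gamma(
                shape=hyper.sigma2_shape + 0.5 * I,
                scale=1.0 / (hyper.sigma2_rate + 0.5 * np.sum(phi**2, axis=0)),
            )

            # spatial autocorrelation alpha (logit-scale Metropolis)
            if hyper.fix_alpha is None and I_ne:
                step = ad_a.step()
                t_cur = logit(alpha)
                t_prop = t_cur + step * rng.standard_normal()
                a_prop = float(expit(t_prop))
                tW = float(np.trace(Lam @ (z.T @ (W @ z))))
                dlog = (
                    0.5 * K * np.sum(np.log1p(-a_prop * omega) - np.log1p(-alpha * omega))
                    + 0.5 * (a_prop - alpha) * tW
                    + np.log(a_prop * (1 - a_prop))
                    - np.log(alpha * (1 - alpha))
                )
                acc = np.log(rng.random()) < dlog
                if acc:
                    alpha = a_prop
                if adapting:
                    ad_a.update(float(acc), it)

            # impute suppressed counts from their exact full conditional,
            # last so the stored (lambda, imputed) pair is coherent
            if len(cells):
                mu = n[rows, kols] * np.exp(eta[rows, kols])
                imputed = _sample_truncated_poisson_many(mu, support, rng)
                ycur[rows, kols] = imputed

            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
                lam_out[stored] = np.exp(eta)
                imp_out[stored] = imputed
                stored += 1
        lam_chains.append(lam_out)
        imp_chains.append(imp_out)

    from .poisson_gamma import _warn_if_unconverged

    _warn_if_unconverged(lam_chains, mcmc)
    return PosteriorDraws(
        lam=np.concatenate(lam_chains, axis=0),
        imputed=np.concatenate(imp_chains, axis=0),
        suppressed_cells=cells,
        area_ids=censored.area_ids,
        ages=censored.ages,
        model_tag="mcar",
    )
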