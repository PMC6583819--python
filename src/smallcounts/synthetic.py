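"""Synthetic study generator.

Produces complete county-by-age count tables with the statistical structure
the models assume — heavily right-skewed populations, age-specific baseline
rates rising steeply with age (so young age groups yield a preponderance of
zero and near-zero counts), spatially correlated and between-age-correlated
log rates — so the whole pipeline (suppression, substitution, both Bayesian
models, comparison) can be exercised without any external data.

Areas live on a rectangular lattice with rook (edge-sharing) adjacency, the
grid analogue of counties sharing a border, and are partitioned into
contiguous column-block "states" so state-level pooling is exercised with
more than one state.  The generative model for rates is exactly the
multivariate-CAR hierarchy: log lambda = base_k + z + phi with z drawn from
the proper MCAR prior by exact multivariate-normal factorization.

The default configuration (20 x 20 lattice, K = 3 age groups) is scaled so
that roughly half of all counts fall below the suppression threshold of 10,
the regime the models are designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .data import (
    AdjacencyGraph,
    CensoredCountTable,
    CountTable,
    StandardPopulation,
    apply_suppression,
    write_adjacency,
    write_censored_table,
    write_count_table,
    write_standard_population,
)


def _default_sigma() -> np.ndarray:
    # between-age covariance of the spatial field: SD 0.4 on the log scale,
    # correlation 0.6 between adjacent-in-age fields, 0.36 otherwise
    corr = np.array([[1.0, 0.6, 0.36], [0.6, 1.0, 0.6], [0.36, 0.6, 1.0]])
    return 0.16 * corr


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults emulate an age-specific chronic-disease mortality table:
    log-normal populations (median ~3,000 persons per area and age group,
    log-SD 1.2), baseline rates of 1, 10 and 50 deaths per 10,000
    person-years across the three age groups, strong spatial autocorrelation
    (alpha = 0.95) and moderate between-age correlation of the spatial
    fields, plus a small exchangeable effect.
    """

    nrow: int = 20
    ncol: int = 20
    K: int = 3
    n_states: int = 4
    ages: tuple[str, ...] | None = None  # default: g1 < g2 < ... (sorted)
    pop_log_mean: float | tuple = 8.0
    pop_log_sd: float | tuple = 1.2
    base_log_rates: tuple = (-6.9, -4.6, -3.0)
    alpha_true: float = 0.95
    Sigma_true: np.ndarray = field(default_factory=_default_sigma)
    sigma_phi: float = 0.1
    std_weights: tuple | None = (0.55, 0.35, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        S = np.asarray(self.Sigma_true, float)
        if S.shape != (self.K, self.K) or not np.allclose(S, S.T):
            raise ValueError("Sigma_true must be symmetric K x K")
        np.linalg.cholesky(S)
        if len(self.base_log_rates) != self.K:
            raise ValueError("base_log_rates must have length K")
        if self.ages is None:
            self.ages = tuple(f"g{k+1}" for k in range(self.K))

    @property
    def I(self) -> int:
        return self.nrow * self.ncol


def _area_name(r: int, c: int, nrow: int, ncol: int) -> str:
    wr = len(str(nrow - 1))
    wc = len(str(ncol - 1))
    return f"a{r:0{wr}d}_{c:0{wc}d}"


def make_lattice(nrow: int, ncol: int) -> AdjacencyGraph:
    """Rook adjacency on an nrow x ncol grid (area names sort row-major)."""
    if nrow < 1 or ncol < 1:
        raise ValueError("lattice dimensions must be >= 1")
    g = nx.grid_2d_graph(nrow, ncol)
    name = {rc: _area_name(rc[0], rc[1], nrow, ncol) for rc in g.nodes}
    nbrs = {
        name[rc]: frozenset(name[o] for o in g.neighbors(rc)) for rc in g.nodes
    }
    return AdjacencyGraph(tuple(sorted(nbrs)), nbrs)


def _draw_mcar_field(
    graph: AdjacencyGraph,
    order: tuple[str, ...],
    alpha: float,
    Sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw of Z (I x K) with Cov(z_ik, z_jl) = (M(alpha)^-1)_ij Sigma_kl.

    Uses the factorization Z = L_M^{-T} E L_Sigma^T with E iid standard
    normal, where M = L_M L_M^T.  Isolated areas (zero M row) receive
    independent N(0, Sigma) rows.
    """
    from .mcar import car_precision

    I, K = len(order), Sigma.shape[0]
    W = graph.adjacency_matrix(order)
    d = np.asarray(W.sum(axis=1)).ravel()
    noniso = d > 0
    E = rng.standard_normal((I, K))
    L_S = cholesky(Sigma, lower=True)
    Z = np.empty((I, K))
    if noniso.any():
        M = car_precision(graph, alpha, order=order).toarray()
        Mnn = M[np.ix_(noniso, noniso)]
        L_M = cholesky(Mnn, lower=True)
        Z[noniso] = solve_triangular(L_M.T, E[noniso], lower=False) @ L_S.T
    if (~noniso).any():
        Z[~noniso] = E[~noniso] @ L_S.T
    return Z


def simulate_table(config: SimConfig) -> tuple[CountTable, np.ndarray]:
    """Simulate a complete count table; returns (table, true I x K rates)."""
    rng = np.random.default_rng(config.seed)
    graph = make_lattice(config.nrow, config.ncol)
    order = graph.areas
    I, K = config.I, config.K

    mu = np.broadcast_to(np.asarray(config.pop_log_mean, float), (K,))
    sd = np.broadcast_to(np.asarray(config.pop_log_sd, float), (K,))
    n = np.ceil(rng.lognormal(mean=mu, sigma=sd, size=(I, K))).astype(np.int64)
    n = np.maximum(n, 1)

    Z = _draw_mcar_field(graph, order, config.alpha_true, np.asarray(config.Sigma_true), rng)
    phi = config.sigma_phi * rng.standard_normal((I, K))
    log_lam = np.asarray(config.base_log_rates)[None, :] + Z + phi
    lam = np.exp(log_lam)
    y = rng.poisson(n * lam)

    # contiguous column-block states; area names sort row-major, so recover
    # the column index from the name
    state_of = {}
    for a in order:
        c = int(a.split("_")[1])
        state_of[a] = f"S{c * config.n_states // config.ncol + 1}"
    table = CountTable(order, state_of, tuple(config.ages), y, n)
    return table, lam


@dataclass(frozen=True)
class StudyBundle:
    """Everything one model-comparison experiment needs."""

    complete: CountTable
    censored: CensoredCountTable
    graph: AdjacencyGraph
    std: StandardPopulation
    truth: np.ndarray  # I x K true rates
    config: SimConfig


def default_study(
    seed: int = 0,
    outdir: str | Path | None = None,
    config: SimConfig | None = None,
    threshold: int = 10,
    zero_visible: bool = False,
) -> StudyBundle:
    """One-call study fixture: simulate, suppress, and optionally write files.

    When ``outdir`` is given, the complete and censored counts CSVs, the
    adjacency neighbor-list file, the standard-population CSV and a truth
    CSV are written there in the package's standard text formats.
    """
    config = config or SimConfig(seed=seed)
    if config.seed != seed:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    table, lam = simulate_table(config)
    graph = make_lattice(config.nrow, config.ncol)
    censored = apply_suppression(table, threshold=threshold, zero_visible=zero_visible)
    w = config.std_weights if config.std_weights is not None else np.ones(config.K)
    if len(w) != config.K:
        raise ValueError("std_weights must have length K")
    std = StandardPopulation(np.asarray(w, float), tuple(config.ages))
    bundle = StudyBundle(table, censored, graph, std, lam, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_count_table(table, outdir / "counts_complete.csv")
        write_censored_table(censored, outdir / "counts_censored.csv")
        write_adjacency(graph, outdir / "adjacency.txt")
        write_standard_population(std, outdir / "standard_population.csv")
        frame = table.to_frame()[["area", "age"]].copy()
        frame["rate"] = lam.ravel()
        frame.to_csv(outdir / "true_rates.csv", index=False, float_format="%.10g")
    return bundle
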