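"""Posterior post-processing.

Age standardization is applied draw-wise, so the uncertainty in every
age-specific rate propagates into the standardized rate without any extra
approximation.  Interval summaries use the 2.5th and 97.5th empirical
percentiles (linear interpolation between order statistics, numpy's
``"linear"`` convention, fixed for bit-reproducibility).

Model comparison uses the deviance information criterion DIC = Dbar + pD,
where Dbar is the posterior mean deviance (fit) and pD = Dbar - D(theta_bar)
the effective number of parameters (complexity).  Under censoring the
default deviance is the observed-data likelihood: a suppressed cell
contributes the probability that the count falls in the censoring set,
which keeps DIC comparable across models that impute differently.  The
augmented complete-data deviance is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data import CensoredCountTable, CountTable, StandardPopulation, STD_AGE_LABEL

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PosteriorDraws:
    """Retained MCMC draws of all cell rates and imputed suppressed counts.

    ``lam`` has shape ``(L, I, K)``; ``imputed`` has shape
    ``(L, n_suppressed)`` with columns ordered by ``suppressed_cells``
    (row-major cell indices into the grid).
    """

    lam: np.ndarray
    imputed: np.ndarray
    suppressed_cells: tuple[tuple[int, int], ...]
    area_ids: tuple[str, ...]
    ages: tuple[str, ...]
    model_tag: str

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim != 3:
            raise ValueError("lam must be (L, I, K)")
        if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
            raise ValueError("all rate draws must be finite and positive")
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "imputed", np.asarray(self.imputed, dtype=np.int64))

    @property
    def L(self) -> int:
        return self.lam.shape[0]

    def subset(self, idx) -> "PosteriorDraws":
        return PosteriorDraws(
            self.lam[idx],
            self.imputed[idx] if self.imputed.size else self.imputed,
            self.suppressed_cells,
            self.area_ids,
            self.ages,
            self.model_tag,
        )


class Summary(NamedTuple):
    median: float
    lower: float
    upper: float


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion decomposition (dic = dbar + pd)."""

    dic: float
    dbar: float
    pd: float
    d_at_mean: float

    def __post_init__(self) -> None:
        assert abs(self.dic - (self.dbar + self.pd)) < 1e-9
        assert abs(self.pd - (self.dbar - self.d_at_mean)) < 1e-9


def standardized_draws(draws: PosteriorDraws, std: StandardPopulation) -> np.ndarray:
    """Per-draw, per-area standardized rates sum_k pi_k lambda_ik^(l)."""
    if draws.lam.shape[2] != std.K:
        raise ValueError("standard population has wrong number of age groups")
    return draws.lam @ std.weights


def summarize(draw_vector) -> Summary:
    """Posterior median and central 95% credible interval."""
    v = np.asarray(draw_vector, dtype=float)
    if v.size < 40:
        raise ValueError("need at least 40 draws to form a 95% interval")
    lo, med, hi = np.percentile(v, [2.5, 50.0, 97.5], method="linear")
    return Summary(float(med), float(lo), float(hi))


def reliability_flag(draw_vector, rse_threshold: float = 0.25) -> bool:
    """True when the posterior relative standard error (SD over median) is
    below ``rse_threshold``.  A rate with median zero is never reliable."""
    v = np.asarray(draw_vector, dtype=float)
    med = float(np.median(v))
    if med == 0:
        return False
    return bool(np.std(v) / med < rse_threshold)


def _poisson_logpmf(y, mu):
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def _observed_deviance(lam2d, censored: CensoredCountTable, chunk: int = 256):
    """Observed-data deviance for each row of lam2d (draws x cells, flattened).

    Unsuppressed cells contribute -2 log Pois(y; n lam); suppressed cells
    contribute -2 log P(count in censoring set).
    """
    mask = censored.suppressed.ravel()
    n = censored.n.ravel().astype(float)
    y = censored.observed.ravel().astype(float)
    support = censored.censor_set().astype(float)
    out = np.empty(lam2d.shape[0])
    lg_support = gammaln(support + 1.0)
    for start in range(0, lam2d.shape[0], chunk):
        lam = lam2d[start : start + chunk]
        mu = lam * n
        ll = np.zeros_like(mu)
        obs = ~mask
        ll[:, obs] = _poisson_logpmf(y[obs], mu[:, obs])
        if mask.any():
            mus = mu[:, mask]  # (chunk, S)
            terms = (
                support[:, None, None] * np.log(mus)[None]
                - mus[None]
                - lg_support[:, None, None]
            )
            ll[:, mask] = logsumexp(terms, axis=0)
        out[start : start + chunk] = -2.0 * ll.sum(axis=1)
    return out


def _complete_deviance(lam2d, counts2d, n):
    mu = lam2d * n
    return -2.0 * _poisson_logpmf(counts2d, mu).sum(axis=1)


def compute_dic(
    draws: PosteriorDraws,
    censored: CensoredCountTable,
    method: str = "observed",
    cells: np.ndarray | None = None,
) -> DICResult:
    """DIC of a fitted model under censoring.

    ``method="observed"`` (default) marginalizes suppressed cells over the
    censoring set; ``method="complete"`` uses the augmented-data deviance at
    each draw's imputed counts (plug-in at the rounded posterior mean count).
    ``cells`` optionally restricts the deviance to a boolean cell mask
    (e.g. one age group).
    """
    L, I, K = draws.lam.shape
    lam2d = draws.lam.reshape(L, I * K)
    sel = np.ones(I * K, dtype=bool) if cells is None else np.asarray(cells).ravel()
    sub = CensoredCountTable(
        tuple(str(j) for j in range(int(sel.sum()))),
        {str(j): "s" for j in range(int(sel.sum()))},
        ("g",),
        censored.observed.ravel()[sel, None],
        censored.n.ravel()[sel, None],
        censored.suppressed.ravel()[sel, None],
        threshold=censored.threshold,
        zero_visible=censored.zero_visible,
    )
    lam_sel = lam2d[:, sel]
    lam_bar = lam_sel.mean(axis=0, keepdims=True)
    if method == "observed":
        dev = _observed_deviance(lam_sel, sub)
        d_at_mean = float(_observed_deviance(lam_bar, sub)[0])
    elif method == "complete":
        counts = np.tile(censored.observed.ravel()[sel].astype(float), (L, 1))
        flat_idx = {
            (i * K + k): c for c, (i, k) in enumerate(draws.suppressed_cells)
        }
        sel_idx = np.flatnonzero(sel)
        for col, j in enumerate(sel_idx):
            if j in flat_idx:
                counts[:, col] = draws.imputed[:, flat_idx[j]]
        n = sub.n.ravel().astype(float)
        dev = _complete_deviance(lam_sel, counts, n)
        d_at_mean = float(
            _complete_deviance(lam_bar, np.round(counts.mean(axis=0))[None], n)[0]
        )
    else:
        raise ValueError("method must be 'observed' or 'complete'")
    dbar = float(dev.mean())
    pd_ = dbar - d_at_mean
    if pd_ < 0:
        logger.warning("negative pD (%.3f): pathological posterior geometry", pd_)
    return DICResult(dic=dbar + pd_, dbar=dbar, pd=pd_, d_at_mean=d_at_mean)


def dic_table(
    draws: PosteriorDraws, censored: CensoredCountTable, method: str = "observed"
) -> pd.DataFrame:
    """Per-age-group and overall DIC decomposition (rows: DIC, Dbar, pD)."""
    I, K = censored.I, censored.K
    cols = {}
    for k, g in enumerate(censored.ages):
        cells = np.zeros((I, K), dtype=bool)
        cells[:, k] = True
        r = compute_dic(draws, censored, method=method, cells=cells)
        cols[g] = [r.dic, r.dbar, r.pd]
    r = compute_dic(draws, censored, method=method)
    cols["overall"] = [r.dic, r.dbar, r.pd]
    return pd.DataFrame(cols, index=["DIC", "Dbar", "pD"])


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def compare_correlations(
    estimates: dict[str, np.ndarray],
    truth: CountTable,
    std: StandardPopulation,
    suppressed: np.ndarray | None = None,
    restrict_to_suppressed: bool = True,
) -> pd.DataFrame:
    """Pearson correlations between estimated and complete-data rates.

    ``estimates`` maps an approach name to an ``I x K`` array of rate
    estimates.  Age-specific columns are computed over suppressed cells only
    when ``restrict_to_suppressed`` (requires the ``suppressed`` mask); the
    standardized column always uses all areas.  Undefined correlations
    (fewer than 3 cells in scope, or zero variance) are reported as NaN.
    """
    true_rates = truth.rates()
    true_std = true_rates @ std.weights
    if restrict_to_suppressed and suppressed is None:
        raise ValueError("restrict_to_suppressed requires the suppression mask")
    rows = {}
    for name, est in estimates.items():
        est = np.asarray(est, float)
        row = {}
        for k, g in enumerate(truth.ages):
            if restrict_to_suppressed:
                m = suppressed[:, k]
                row[g] = _pearson(est[m, k], true_rates[m, k])
            else:
                row[g] = _pearson(est[:, k], true_rates[:, k])
        row[STD_AGE_LABEL] = _pearson(est @ std.weights, true_std)
        rows[name] = row
    return pd.DataFrame(rows).T


def estimate_table(
    draws: PosteriorDraws,
    std: StandardPopulation,
    rse_threshold: float = 0.25,
) -> pd.DataFrame:
    """Full estimates table: per (area, age) and per-area standardized rows,
    each with posterior median, 95% interval and reliability flag."""
    L, I, K = draws.lam.shape
    rows = []
    std_draws = standardized_draws(draws, std)
    for i, a in enumerate(draws.area_ids):
        for k, g in enumerate(draws.ages):
            v = draws.lam[:, i, k]
            s = summarize(v)
            rows.append((a, g, s.median, s.lower, s.upper, reliability_flag(v, rse_threshold)))
        v = std_draws[:, i]
        s = summarize(v)
        rows.append((a, STD_AGE_LABEL, s.median, s.lower, s.upper, reliability_flag(v, rse_threshold)))
    return pd.DataFrame(
        rows, columns=["area", "age", "estimate", "lower", "upper", "reliable"]
    )
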