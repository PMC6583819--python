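"""Substitution baseline for suppressed counts.

Each suppressed count is replaced with the expected count implied by the
state-wide average rate for that age group,

    y*_ik = lambda_bar(s_i, k) * n_ik,

where lambda_bar(s, k) pools events over all areas of state ``s``.  The
substituted table yields point estimates only; by construction this path
carries no measure of uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CensoredCountTable, CountTable, StandardPopulation


@dataclass(frozen=True)
class StateRateTable:
    """State-by-age pooled rates with their numerator/denominator totals."""

    rate: dict[tuple[str, str], float]
    events: dict[tuple[str, str], float]
    population: dict[tuple[str, str], int]

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.rate[key]


def state_age_rates(table: CountTable) -> StateRateTable:
    """Pooled state-wide rates: sum of events over sum of population.

    Runs on a complete table; in real use the state totals are assumed
    publicly available and may instead be supplied directly as a
    :class:`StateRateTable`.
    """
    rate: dict[tuple[str, str], float] = {}
    events: dict[tuple[str, str], float] = {}
    pop: dict[tuple[str, str], int] = {}
    areas = np.array(table.area_ids)
    states = np.array([table.state_of[a] for a in table.area_ids])
    for s in table.states:
        rows = states == s
        y_s = np.asarray(table.y)[rows].sum(axis=0)
        n_s = np.asarray(table.n)[rows].sum(axis=0)
        if np.any(n_s <= 0):
            raise ValueError(f"state {s!r} has zero total population")
        for k, g in enumerate(table.ages):
            rate[(s, g)] = float(y_s[k]) / float(n_s[k])
            events[(s, g)] = float(y_s[k])
            pop[(s, g)] = int(n_s[k])
    return StateRateTable(rate, events, pop)


def substitute_suppressed(
    censored: CensoredCountTable, rates: StateRateTable
) -> CountTable:
    """Fill suppressed cells with ``rate * population``.

    Unsuppressed cells are untouched.  Substituted values are kept as real
    numbers (no rounding, no capping at the suppression bound), matching the
    substitution rule as stated.  Idempotent: a table with no suppressed
    cells passes through unchanged apart from the ``substituted`` flag.
    """
    y = censored.observed.astype(float).copy()
    for i, a in enumerate(censored.area_ids):
        s = censored.state_of[a]
        for k, g in enumerate(censored.ages):
            if censored.suppressed[i, k]:
                if (s, g) not in rates.rate:
                    raise KeyError(f"no state rate for ({s!r}, {g!r})")
                y[i, k] = rates.rate[(s, g)] * censored.n[i, k]
    return CountTable(
        censored.area_ids,
        dict(censored.state_of),
        censored.ages,
        y,
        censored.n,
        substituted=True,
    )


def direct_standardized_rate(age_rates, std: StandardPopulation) -> float:
    """Directly age-standardized rate: sum_k pi_k * lambda_k."""
    lam = np.asarray(age_rates, dtype=float)
    if lam.shape[-1] != std.K:
        raise ValueError(
            f"expected {std.K} age-specific rates, got {lam.shape[-1]}"
        )
    return float(lam @ std.weights) if lam.ndim == 1 else lam @ std.weights


def standardized_rates(table: CountTable, std: StandardPopulation) -> np.ndarray:
    """Per-area standardized rates from a table's crude (or substituted) rates."""
    return table.rates() @ std.weights
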