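"""Core data containers and text-format I/O.

The package works with complete county-by-age count tables (events ``y_ik``
and populations ``n_ik``), their censored counterparts in which small counts
are suppressed, an area adjacency structure, and a standard-population age
distribution used for direct age standardization.

All readers enforce a deterministic (lexicographic) ordering of areas and
age groups so that every matrix produced downstream is reproducible across
runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Token written in place of the count for suppressed cells.
SUPPRESSED_TOKEN = "Suppressed"

COUNT_COLUMNS = ["area", "state", "age", "count", "population"]


@dataclass(frozen=True)
class CountTable:
    """Complete area-by-age grid of event counts and populations.

    Parameters
    ----------
    area_ids
        Sorted area identifiers (length ``I``).
    state_of
        Map from area id to the state the area belongs to.
    ages
        Sorted age-group labels (length ``K``).
    y
        ``I x K`` event counts.  Integer-valued unless ``substituted`` is
        true, in which case suppressed cells may carry real-valued
        substitution estimates.
    n
        ``I x K`` positive integer population sizes.
    substituted
        Flag marking tables produced by the substitution baseline.
    """

    area_ids: tuple[str, ...]
    state_of: dict[str, str]
    ages: tuple[str, ...]
    y: np.ndarray
    n: np.ndarray
    substituted: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        n = np.asarray(self.n)
        I, K = len(self.area_ids), len(self.ages)
        if y.shape != (I, K) or n.shape != (I, K):
            raise ValueError(
                f"y/n must have shape ({I}, {K}); got {y.shape} and {n.shape}"
            )
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("counts must be finite and nonnegative")
        if not self.substituted and np.any(y != np.round(y)):
            raise ValueError("counts must be integers in an unsubstituted table")
        if np.any(n < 1) or np.any(n != np.round(n)):
            raise ValueError("populations must be integers >= 1")
        missing = set(self.area_ids) - set(self.state_of)
        if missing:
            raise ValueError(f"areas without a state label: {sorted(missing)}")
        object.__setattr__(self, "y", y if self.substituted else y.astype(np.int64))
        object.__setattr__(self, "n", n.astype(np.int64))

    @property
    def I(self) -> int:
        return len(self.area_ids)

    @property
    def K(self) -> int:
        return len(self.ages)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.state_of[a] for a in self.area_ids)))

    def rates(self) -> np.ndarray:
        """Crude rates ``y_ik / n_ik``."""
        return np.asarray(self.y, dtype=float) / self.n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for k, g in enumerate(self.ages):
                rows.append((a, self.state_of[a], g, self.y[i, k], self.n[i, k]))
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@dataclass(frozen=True)
class CensoredCountTable:
    """A count table in which small counts are suppressed (left-censored).

    Suppressed cells carry no value; only the interval containing the count
    is known.  With ``zero_visible=False`` a suppressed count lies in
    ``{0, ..., threshold-1}``; with ``zero_visible=True`` exact zeros are
    reported, so a suppressed count lies in ``{1, ..., threshold-1}``.
    """

    area_ids: tuple[str, ...]
    state_of: dict[str, str]
    ages: tuple[str, ...]
    observed: np.ndarray  # int64; -1 in suppressed cells
    n: np.ndarray
    suppressed: np.ndarray  # bool mask
    threshold: int = 10
    zero_visible: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        obs = np.asarray(self.observed, dtype=np.int64)
        mask = np.asarray(self.suppressed, dtype=bool)
        shown = obs[~mask]
        lo = 0 if self.zero_visible else self.threshold
        if shown.size and self.zero_visible:
            bad = (shown != 0) & (shown < self.threshold)
            if np.any(bad):
                raise ValueError("visible counts must be 0 or >= threshold")
        elif shown.size and np.any(shown < lo):
            raise ValueError("visible counts must be >= threshold")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "n", np.asarray(self.n, dtype=np.int64))
        object.__setattr__(self, "suppressed", mask)

    @property
    def I(self) -> int:
        return len(self.area_ids)

    @property
    def K(self) -> int:
        return len(self.ages)

    def censor_set(self) -> np.ndarray:
        """Integer support of a suppressed count."""
        lo = 1 if self.zero_visible else 0
        return np.arange(lo, self.threshold)

    def n_suppressed(self) -> int:
        return int(self.suppressed.sum())


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric neighbor structure over the areas (no self-loops)."""

    areas: tuple[str, ...]
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        aset = set(self.areas)
        for a, nb in self.neighbors.items():
            if a in nb:
                raise ValueError(f"self-loop at area {a!r}")
            for b in nb:
                if b not in aset:
                    raise ValueError(f"unknown neighbor {b!r} of area {a!r}")
                if a not in self.neighbors.get(b, frozenset()):
                    raise ValueError(f"asymmetric adjacency: {a!r} -> {b!r}")

    @property
    def degree(self) -> dict[str, int]:
        return {a: len(self.neighbors.get(a, frozenset())) for a in self.areas}

    def adjacency_matrix(self, order: tuple[str, ...] | None = None):
        """Sparse 0/1 adjacency matrix W in the given area order."""
        from scipy import sparse

        order = tuple(order) if order is not None else self.areas
        idx = {a: i for i, a in enumerate(order)}
        rows, cols = [], []
        for a in order:
            for b in self.neighbors.get(a, frozenset()):
                rows.append(idx[a])
                cols.append(idx[b])
        I = len(order)
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(I, I)
        )


@dataclass(frozen=True)
class StandardPopulation:
    """Standard-population age weights pi_k used for direct standardization."""

    weights: np.ndarray
    ages: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "weights", w / total)

    @property
    def K(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _grid_from_frame(df: pd.DataFrame, path) -> tuple:
    dup = df.duplicated(subset=["area", "age"], keep=False)
    if dup.any():
        cells = sorted(set(map(tuple, df.loc[dup, ["area", "age"]].values)))
        raise ValueError(f"duplicate (area, age) rows in {path}: {cells}")
    areas = tuple(sorted(df["area"].unique()))
    ages = tuple(sorted(df["age"].unique()))
    expected = {(a, g) for a in areas for g in ages}
    present = set(map(tuple, df[["area", "age"]].values))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"incomplete grid in {path}; missing cells: {missing}")
    state_of = {}
    for a, sub in df.groupby("area"):
        st = sub["state"].unique()
        if len(st) > 1:
            raise ValueError(f"area {a!r} mapped to multiple states: {sorted(st)}")
        state_of[a] = st[0]
    return areas, ages, state_of


def read_count_table(path) -> CountTable:
    """Read a complete counts CSV (columns area,state,age,count,population).

    Row order in the file is irrelevant; areas and ages are sorted.  A file
    containing suppressed cells must be read with :func:`read_censored_table`.
    """
    df = pd.read_csv(path, dtype={"area": str, "state": str, "age": str})
    missing_cols = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df["count"].astype(str).str.strip().eq(SUPPRESSED_TOKEN).any():
        raise ValueError(
            f"{path} contains suppressed cells; use read_censored_table"
        )
    counts = pd.to_numeric(df["count"], errors="raise")
    if not np.all(counts == np.round(counts)):
        bad = df.loc[counts != np.round(counts), ["area", "age"]]
        raise ValueError(f"non-integer counts at {bad.values.tolist()}")
    areas, ages, state_of = _grid_from_frame(df, path)
    ai = {a: i for i, a in enumerate(areas)}
    gi = {g: k for k, g in enumerate(ages)}
    y = np.zeros((len(areas), len(ages)), dtype=np.int64)
    n = np.zeros_like(y)
    for row, c in zip(df.itertuples(index=False), counts):
        y[ai[row.area], gi[row.age]] = int(c)
        n[ai[row.area], gi[row.age]] = int(row.population)
    return CountTable(areas, state_of, ages, y, n)


def read_censored_table(path, threshold: int = 10, zero_visible: bool = False) -> CensoredCountTable:
    """Read a counts CSV in which suppressed cells hold the literal token
    ``"Suppressed"``."""
    df = pd.read_csv(path, dtype={"area": str, "state": str, "age": str, "count": str})
    missing_cols = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    areas, ages, state_of = _grid_from_frame(df, path)
    ai = {a: i for i, a in enumerate(areas)}
    gi = {g: k for k, g in enumerate(ages)}
    I, K = len(areas), len(ages)
    obs = np.zeros((I, K), dtype=np.int64)
    n = np.zeros((I, K), dtype=np.int64)
    mask = np.zeros((I, K), dtype=bool)
    for row in df.itertuples(index=False):
        i, k = ai[row.area], gi[row.age]
        n[i, k] = int(row.population)
        tok = str(row.count).strip()
        if tok == SUPPRESSED_TOKEN:
            mask[i, k] = True
            obs[i, k] = -1
        else:
            val = float(tok)
            if val != round(val):
                raise ValueError(f"non-integer count at ({row.area}, {row.age})")
            obs[i, k] = int(val)
    return CensoredCountTable(
        areas, state_of, ages, obs, n, mask, threshold=threshold, zero_visible=zero_visible
    )


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_censored_table(censored: CensoredCountTable, path) -> None:
    rows = []
    for i, a in enumerate(censored.area_ids):
        for k, g in enumerate(censored.ages):
            val = (
                SUPPRESSED_TOKEN
                if censored.suppressed[i, k]
                else str(int(censored.observed[i, k]))
            )
            rows.append((a, censored.state_of[a], g, val, censored.n[i, k]))
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, index=False)


def read_adjacency(path, reference_areas=None) -> AdjacencyGraph:
    """Read a neighbor-list file: one line per area, ``"area: n1 n2 ..."``.

    The graph is symmetrized on read; if the input lists ``j`` as a neighbor
    of ``i`` but not vice versa, ``i`` is added to ``j``'s list and a warning
    is logged.  Areas with an empty neighbor list (islands) are allowed.
    """
    listed: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, _, rest = line.partition(":")
            name = name.strip()
            nbrs = set(rest.split())
            if name in nbrs:
                raise ValueError(f"self-loop at area {name!r}")
            listed.setdefault(name, set()).update(nbrs)
    areas = set(listed)
    for nb in listed.values():
        areas |= nb
    if reference_areas is not None:
        unknown = areas - set(reference_areas)
        if unknown:
            raise ValueError(f"unknown areas in adjacency file: {sorted(unknown)}")
        areas |= set(reference_areas)
    sym: dict[str, set[str]] = {a: set(listed.get(a, set())) for a in areas}
    warned = False
    for a in sorted(areas):
        for b in sym[a]:
            if a not in sym[b]:
                sym[b].add(a)
                if not warned:
                    logger.warning(
                        "asymmetric adjacency input (e.g. %r lists %r but not "
                        "vice versa); symmetrized", a, b
                    )
                    warned = True
    return AdjacencyGraph(
        tuple(sorted(areas)), {a: frozenset(nb) for a, nb in sym.items()}
    )


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        for a in graph.areas:
            fh.write(f"{a}: {' '.join(sorted(graph.neighbors.get(a, frozenset())))}\n")


def read_standard_population(path) -> StandardPopulation:
    """Read an ``age,weight`` CSV; weights are renormalized to sum to 1."""
    df = pd.read_csv(path, dtype={"age": str})
    df = df.sort_values("age")
    return StandardPopulation(df["weight"].to_numpy(float), tuple(df["age"]))


def write_standard_population(std: StandardPopulation, path) -> None:
    ages = std.ages or tuple(f"g{k}" for k in range(std.K))
    pd.DataFrame({"age": ages, "weight": std.weights}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# suppression operator
# ---------------------------------------------------------------------------


def apply_suppression(
    table: CountTable, threshold: int = 10, zero_visible: bool = False
) -> CensoredCountTable:
    """Censor all counts below ``threshold``.

    With ``zero_visible=True`` exact zeros remain visible (the convention of
    data systems that display zero cells); otherwise zeros are suppressed
    along with counts ``1..threshold-1``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    y = np.asarray(table.y)
    mask = y < threshold
    if zero_visible:
        mask &= y > 0
    obs = np.where(mask, -1, y).astype(np.int64)
    return CensoredCountTable(
        table.area_ids,
        dict(table.state_of),
        table.ages,
        obs,
        table.n,
        mask,
        threshold=threshold,
        zero_visible=zero_visible,
    )


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

#: The "age" value that marks an age-standardized row in an estimates CSV.
STD_AGE_LABEL = "std"

ESTIMATE_COLUMNS = ["area", "age", "estimate", "lower", "upper", "reliable"]


def write_estimates(summaries: pd.DataFrame, path) -> None:
    """Write an estimates table (age-specific and standardized rows).

    Standardized rows use the ``age`` value ``"std"``.  Floats are written
    with 10 significant digits so the file round-trips losslessly.
    """
    missing = [c for c in ESTIMATE_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"estimates table missing columns {missing}")
    summaries[ESTIMATE_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"area": str, "age": str})
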