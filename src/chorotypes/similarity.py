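"""Baroni-Urbani & Buser similarity, its null distribution, and trinary
significance matrices.

For two binary vectors over ``n`` attributes, with ``a``/``b`` presences
unique to each vector, ``c`` shared presences and ``d`` shared absences, the
Baroni-Urbani & Buser index is

    S = (sqrt(c * d) + c) / (sqrt(c * d) + a + b + c)

Shared absences enter only multiplied by shared presences, so two vectors can
never look similar through joint absence alone: ``S = 0`` whenever ``c = 0``.

Observed similarities are classified against a null distribution of the index
as significantly high (+1), significantly low (−1), or neither (0).  The
default null treats each attribute as landing in one of the four cells
(a, b, c, d) independently with equal probability (exact multinomial
enumeration); a hypergeometric scheme conditioning on the two row totals and
a user-supplied critical-value table are available as alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core_io import PresenceAbsenceTable

__all__ = [
    "PairCounts",
    "pair_counts",
    "bub_similarity",
    "jaccard_similarity",
    "sorensen_similarity",
    "SIMILARITY_INDICES",
    "SimilarityMatrix",
    "similarity_matrix",
    "NullDistribution",
    "null_distribution",
    "classify_pair",
    "TrinarySignificanceMatrix",
    "significance_matrix",
    "load_critical_values",
]

#: Absolute tolerance for comparing attainable similarity values when
#: accumulating discrete tail mass.
_TIE_TOL = 1e-12

#: Largest attribute count for which the unconditional null is built by exact
#: composition enumeration (C(n+3, 3) terms); Monte Carlo beyond.
_MAX_EXACT_N = 60


class PairCounts(NamedTuple):
    """2×2 match/mismatch counts for one pair of binary vectors."""

    a: int  #: unique to the first vector
    b: int  #: unique to the second vector
    c: int  #: shared presences
    d: int  #: shared absences

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def pair_counts(u, v) -> PairCounts:
    """Count a, b, c, d for two equal-length binary vectors."""
    u = np.asarray(u, dtype=np.int8)
    v = np.asarray(v, dtype=np.int8)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {u.shape} vs {v.shape}")
    c = int(np.sum((u == 1) & (v == 1)))
    d = int(np.sum((u == 0) & (v == 0)))
    a = int(np.sum(u)) - c
    b = int(np.sum(v)) - c
    return PairCounts(a, b, c, d)


def bub_similarity(counts: PairCounts) -> float:
    """Baroni-Urbani & Buser similarity for one pair of counts.

    Undefined (raises) only when both vectors are empty (a=b=c=0, d may be
    anything only through c=0, d>0 handled by the c=0 rule upstream of the
    degenerate case a=b=c=d=0).
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative pair counts: {counts}")
    if c == 0:
        if a + b == 0:
            raise ValueError("similarity undefined for two empty vectors (a=b=c=0)")
        return 0.0
    root = math.sqrt(c * d)
    return (root + c) / (root + a + b + c)


def jaccard_similarity(counts: PairCounts) -> float:
    return counts.c / (counts.a + counts.b + counts.c)


def sorensen_similarity(counts: PairCounts) -> float:
    return 2 * counts.c / (counts.a + counts.b + 2 * counts.c)


#: Extension point: alternative binary indices keyed by name.
SIMILARITY_INDICES = {
    "baroni_urbani_buser": bub_similarity,
    "jaccard": jaccard_similarity,
    "sorensen": sorensen_similarity,
}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity matrix with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    mode: str = "Q"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if vals.shape != (k, k):
            raise ValueError(f"matrix shape {vals.shape} does not match {k} labels")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise ValueError("similarity matrix must have unit diagonal")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        if self.mode not in ("Q", "R"):
            raise ValueError(f"mode must be 'Q' or 'R', got {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.labels), columns=list(self.labels))

    def distance(self) -> pd.DataFrame:
        """Complement dissimilarity 1 − S (zero diagonal)."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=list(self.labels), columns=list(self.labels))


def _mode_vectors(table: PresenceAbsenceTable, mode: str):
    """Objects-as-rows view: Q compares unit columns, R compares species rows."""
    if mode == "Q":
        return table.cells.T, table.unit_labels
    if mode == "R":
        return table.cells, table.species_labels
    raise ValueError(f"mode must be 'Q' or 'R', got {mode!r}")


def similarity_matrix(table: PresenceAbsenceTable, mode: str = "Q",
                      index: str = "baroni_urbani_buser") -> SimilarityMatrix:
    """All pairwise similarities among units (Q-mode) or species (R-mode)."""
    X, labels = _mode_vectors(table, mode)
    fn = SIMILARITY_INDICES[index]
    k = X.shape[0]
    S = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            S[i, j] = S[j, i] = fn(pair_counts(X[i], X[j]))
    return SimilarityMatrix(labels, S, mode)


@dataclass(frozen=True)
class NullDistribution:
    """Discrete null distribution of a similarity index.

    ``support`` is sorted ascending; ``probabilities`` matches it and sums to
    one.  ``scheme`` records how the distribution was built.
    """

    support: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    scheme: str
    n: int
    r1: int | None = None
    r2: int | None = None

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=float)
        pr = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "probabilities", pr)
        if sup.shape != pr.shape:
            raise ValueError("support and probabilities must have equal length")
        if abs(pr.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {pr.sum()!r}, not 1")
        if sup.size and (sup.min() < -_TIE_TOL or sup.max() > 1 + _TIE_TOL):
            raise ValueError("support values must lie in [0, 1]")

    def upper_tail(self, s: float) -> float:
        """P(S_null >= s), inclusive of the observed value's own mass."""
        return float(self.probabilities[self.support >= s - _TIE_TOL].sum())

    def lower_tail(self, s: float) -> float:
        """P(S_null <= s), inclusive."""
        return float(self.probabilities[self.support <= s + _TIE_TOL].sum())


def _aggregate(values, probs) -> tuple[np.ndarray, np.ndarray]:
    agg: dict[float, float] = {}
    for s, p in zip(values, probs):
        key = round(float(s), 12)
        agg[key] = agg.get(key, 0.0) + p
    sup = np.array(sorted(agg))
    return sup, np.array([agg[s] for s in sup])


def _null_similarity(a: int, b: int, c: int, d: int) -> float:
    # Under the null the all-absent composition (a=b=c=0) is attainable and
    # maps to 0 through the c = 0 rule.
    if c == 0:
        return 0.0
    root = math.sqrt(c * d)
    return (root + c) / (root + a + b + c)


def null_distribution(n: int, scheme: str = "unconditional",
                      r1: int | None = None, r2: int | None = None,
                      n_monte_carlo: int = 200_000, seed: int = 0) -> NullDistribution:
    """Null distribution of the index over ``n`` attributes.

    ``unconditional``
        Each attribute independently lands in one of the four cells
        (a, b, c, d) with probability 1/4; the distribution over compositions
        is multinomial and is enumerated exactly for ``n <= 60`` (seeded
        Monte Carlo beyond that).
    ``conditional``
        The two row totals ``r1``, ``r2`` are fixed; the shared-presence
        count ``c`` is hypergeometric and determines a, b, d.
    """
    if n < 1:
        raise ValueError(f"attribute count must be >= 1, got {n}")
    if scheme == "unconditional":
        if n <= _MAX_EXACT_N:
            logfact = [math.lgamma(i + 1) for i in range(n + 1)]
            log4n = n * math.log(4)
            values, probs = [], []
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        lp = logfact[n] - logfact[a] - logfact[b] - logfact[c] - logfact[d]
                        values.append(_null_similarity(a, b, c, d))
                        probs.append(math.exp(lp - log4n))
        else:
            rng = np.random.default_rng(seed)
            cells = rng.multinomial(n, [0.25] * 4, size=n_monte_carlo)
            values = [_null_similarity(*row) for row in cells]
            probs = np.full(n_monte_carlo, 1.0 / n_monte_carlo)
        sup, pr = _aggregate(values, probs)
        return NullDistribution(sup, pr, scheme, n)
    if scheme == "conditional":
        if r1 is None or r2 is None:
            raise ValueError("conditional scheme requires r1 and r2")
        if not (0 <= r1 <= n and 0 <= r2 <= n):
            raise ValueError(f"row totals must lie in [0, {n}], got r1={r1}, r2={r2}")
        from scipy.stats import hypergeom

        cs = np.arange(max(0, r1 + r2 - n), min(r1, r2) + 1)
        probs = hypergeom.pmf(cs, n, r1, r2)
        values = [_null_similarity(r1 - c, r2 - c, c, n - r1 - r2 + c) for c in cs]
        sup, pr = _aggregate(values, probs / probs.sum())
        return NullDistribution(sup, pr, scheme, n, r1, r2)
    raise ValueError(f"unknown null scheme: {scheme!r}")


def classify_pair(s_obs: float, null: NullDistribution, alpha: float = 0.05) -> int:
    """Trinary classification of an observed similarity against a null.

    +1 when the inclusive upper-tail mass is below ``alpha``; −1 when the
    inclusive lower-tail mass is; 0 otherwise.  A degenerate null (single
    support point) always yields 0.
    """
    if not 0 < alpha < 0.5:
        raise ValueError(f"alpha must lie in (0, 0.5), got {alpha}")
    if not -_TIE_TOL <= s_obs <= 1 + _TIE_TOL:
        raise ValueError(f"similarity must lie in [0, 1], got {s_obs}")
    if null.upper_tail(s_obs) < alpha:
        return 1
    if null.lower_tail(s_obs) < alpha:
        return -1
    return 0


@dataclass(frozen=True)
class TrinarySignificanceMatrix:
    """Pairwise {+1, 0, −1} classification; the diagonal is ignored."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    alpha: float = 0.05
    scheme: str = "unconditional"
    mode: str = "Q"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if vals.shape != (k, k):
            raise ValueError(f"matrix shape {vals.shape} does not match {k} labels")
        off = vals[~np.eye(k, dtype=bool)]
        if not np.isin(off, (-1, 0, 1)).all():
            raise ValueError("entries must be in {+1, 0, -1}")
        if not (vals == vals.T).all():
            raise ValueError("significance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.labels), columns=list(self.labels))

    def value(self, label_i: str, label_j: str) -> int:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return int(self.values[i, j])


def load_critical_values(path) -> pd.DataFrame:
    """Read a critical-value table CSV with columns ``n``, ``lower``, ``upper``."""
    table = pd.read_csv(path)
    missing = {"n", "lower", "upper"} - set(table.columns)
    if missing:
        raise ValueError(f"critical-value table missing columns: {sorted(missing)}")
    return table.set_index("n")


def significance_matrix(sim: SimilarityMatrix, table: PresenceAbsenceTable,
                        alpha: float = 0.05, scheme: str = "unconditional",
                        critical_values: pd.DataFrame | None = None,
                        ) -> TrinarySignificanceMatrix:
    """Element-wise classification of a similarity matrix.

    The attribute count ``n`` (and, for the conditional scheme, the per-pair
    row totals) is taken from the presence–absence table the similarities
    were computed from.  With ``scheme="table"`` an explicit critical-value
    table is used instead: +1 above ``upper``, −1 below ``lower`` (strict).
    """
    X, labels = _mode_vectors(table, sim.mode)
    if labels != sim.labels:
        raise ValueError("similarity matrix labels do not match the table for its mode")
    n = X.shape[1]
    k = len(labels)
    out = np.zeros((k, k), dtype=np.int8)

    if scheme == "table":
        if critical_values is None:
            raise ValueError("scheme='table' requires a critical-value table")
        try:
            lower = float(critical_values.loc[n, "lower"])
            upper = float(critical_values.loc[n, "upper"])
        except KeyError:
            raise ValueError(f"critical-value table has no row for n={n}") from None
        for i in range(k):
            for j in range(i + 1, k):
                s = sim.values[i, j]
                cls = 1 if s > upper + _TIE_TOL else (-1 if s < lower - _TIE_TOL else 0)
                out[i, j] = out[j, i] = cls
        return TrinarySignificanceMatrix(labels, out, alpha, scheme, sim.mode)

    if scheme == "unconditional":
        null = null_distribution(n, scheme)
        nulls = {}
    elif scheme == "conditional":
        null = None
        nulls = {}
    else:
        raise ValueError(f"unknown null scheme: {scheme!r}")

    row_totals = X.sum(axis=1)
    for i in range(k):
        for j in range(i + 1, k):
            if scheme == "conditional":
                key = tuple(sorted((int(row_totals[i]), int(row_totals[j]))))
                if key not in nulls:
                    nulls[key] = null_distribution(n, "conditional", key[0], key[1])
                pair_null = nulls[key]
            else:
                pair_null = null
            cls = classify_pair(sim.values[i, j], pair_null, alpha)
            out[i, j] = out[j, i] = cls
    return TrinarySignificanceMatrix(labels, out, alpha, scheme, sim.mode)
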