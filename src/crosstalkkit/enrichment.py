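"""Over-representation analysis: exact hypergeometric tails and BH-FDR.

The test is the one-sided Fisher exact test for a 2x2 table with fixed
margins, i.e. the upper tail of a hypergeometric distribution: given a
background of ``N`` genes of which ``K`` belong to a term, and a query of
``n`` genes of which ``k`` hit the term, the enrichment p-value is

    p = P(X >= k),   X ~ Hypergeom(N, K, n).

Tails are computed exactly (integer arithmetic for moderate ``N``,
log-space summation otherwise); no normal approximation is used anywhere,
so p-values as small as 1e-44 survive.  Multiple testing is corrected with
the Benjamini-Hochberg step-up procedure, applied separately within each
ontology/functional-class stratum.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayDB

__all__ = [
    "Universe",
    "EnrichmentRecord",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich",
    "enrichment_table",
]

# Below this background size the tail is summed in exact integer arithmetic
# (correctly rounded on conversion to float); above it, big-integer products
# get slow and a log-space route with ~1e-13 relative accuracy takes over.
_EXACT_INT_MAX_N = 200


def _validate_margins(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if N <= 0:
        raise ValueError("background size N must be positive")
    if not 0 <= K <= N:
        raise ValueError(f"term size K={K} outside [0, N={N}]")
    if not 0 <= n <= N:
        raise ValueError(f"query size n={n} outside [0, N={N}]")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.

    Parameters
    ----------
    k : observed overlap count.
    K : number of "success" genes (term members) in the background.
    n : number of draws (query size).
    N : background size.

    Returns
    -------
    float
        The upper-tail probability, exact up to floating-point rounding.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    _validate_margins(k, K, n, N)
    lo = max(0, n - (N - K))  # smallest achievable overlap
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if N <= _EXACT_INT_MAX_N:
        num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
        return num / math.comb(N, n)
    log_denom = _log_binom(N, n)
    logs = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
    ]
    m = max(logs)
    total = m + math.log(math.fsum(math.exp(x - m) for x in logs))
    return min(1.0, math.exp(total))


def _upper_tail_all(K: int, n: int, N: int) -> list[float]:
    """Upper-tail probabilities for every ``k`` in ``0..min(K, n)``.

    Single pass over the pmf (suffix sums); used by the exhaustive
    verification scans where calling :func:`hypergeom_upper_tail` per ``k``
    would be quadratic.
    """
    _validate_margins(0, K, n, N)
    hi = min(K, n)
    if N <= _EXACT_INT_MAX_N:
        denom = math.comb(N, n)
        num = 0
        out = [0.0] * (hi + 1)
        for i in range(hi, -1, -1):
            num += math.comb(K, i) * math.comb(N - K, n - i)
            out[i] = num / denom
        return [min(1.0, p) for p in out]
    log_denom = _log_binom(N, n)
    logs = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom for i in range(hi + 1)
    ]
    m = max(logs)
    out = [0.0] * (hi + 1)
    acc = 0.0
    for i in range(hi, -1, -1):
        acc += math.exp(logs[i] - m)
        out[i] = min(1.0, math.exp(m + math.log(acc)))
    return out


def bh_adjust(p_values: Sequence[float], m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``m_total`` overrides the family size: with ``m_total > len(p_values)``
    the untested (implicitly p = 1) hypotheses still inflate the correction,
    which is how terms with zero query overlap are accounted for without
    emitting records for them.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total={m} smaller than number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class Universe:
    """Background for the exact test: total size ``N`` and the query set."""

    background_size: int
    query: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", frozenset(self.query))
        if self.background_size <= 0:
            raise ValueError("background_size must be positive")
        if len(self.query) > self.background_size:
            raise ValueError("query larger than the background")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation result."""

    term_id: str
    ontology: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float


def enrich(
    query: Iterable[str],
    db: PathwayDB,
    universe: Universe | int,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every term in ``db`` for over-representation of ``query``.

    BH correction is applied separately within each ontology (functional
    class) stratum; the per-stratum family size counts *all* terms of the
    stratum, including those with zero query overlap, which are not emitted.
    Records are sorted by raw p-value (ties by term id).

    ``alpha`` is carried for callers that threshold on ``p_adj``; no record
    is dropped because of it.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if len(db) == 0:
        raise ValueError("empty pathway collection")
    qset = frozenset(query)
    if isinstance(universe, Universe):
        N = universe.background_size
    else:
        N = int(universe)
        universe = Universe(N, qset)
    if not qset:
        warnings.warn("empty query: no enrichment records produced")
        return []
    n = len(qset)
    if n > N:
        raise ValueError("query larger than the background")

    hits: list[tuple[str, str, int, int, float]] = []
    stratum_sizes: dict[str, int] = {}
    for name, entry in db.items():
        stratum = entry.functional_class
        stratum_sizes[stratum] = stratum_sizes.get(stratum, 0) + 1
        K = len(entry.genes)
        k = len(entry.genes & qset)
        if k >= 1:
            p = hypergeom_upper_tail(k, K, n, N)
            hits.append((name, stratum, k, K, p))

    # BH within each ontology stratum, m_total = all terms of the stratum.
    p_adj: dict[str, float] = {}
    for stratum, m in stratum_sizes.items():
        members = [h for h in hits if h[1] == stratum]
        if not members:
            continue
        adj = bh_adjust([h[4] for h in members], m_total=m)
        for h, q in zip(members, adj):
            p_adj[h[0]] = float(q)

    records = [
        EnrichmentRecord(name, stratum, k, K, n, N, p, p_adj[name])
        for name, stratum, k, K, p in hits
    ]
    records.sort(key=lambda r: (r.p_raw, r.term_id))
    return records


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate records with the standard column layout."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "ontology": r.ontology,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
            }
            for r in records
        ],
        columns=["term_id", "ontology", "k", "K", "n", "N", "p_raw", "p_adj"],
    )
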