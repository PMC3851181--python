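"""Numerical and statistical operators.

* hypergeometric association: the point mass
  ``C(D,k) * C(N-D,n-k) / C(N,n)`` and its upper tail ``P[X >= k]``
* precision / recall of a selected probe set against a reference set
* trajectory volatility ``V(T) = sum |e_i - e_{i-1}|``
* linear trend ``L(T) = sum (e_i - e_{i-1}) = e_N - e_1``

The point mass and tail are computed with exact integer arithmetic up to a
size cutoff and in log-space (``lgamma``) beyond it, so small cases are
correct to the last ulp and large cases never overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataio import AnnotationSet
from .preprocess import AggregatedDataset, DiscretizedTrajectorySet

#: largest N handled with exact integer combinatorics before the lgamma fallback
_EXACT_N_LIMIT = 20_000


@dataclass
class EnrichmentResult:
    """Association of a selected probe set with one named set.

    ``N`` universe size, ``D`` probes in the set, ``n`` selected probes,
    ``k`` overlap; ``p_point`` is the hypergeometric point mass, ``p_tail``
    the upper-tail p-value, ``q`` the optional Benjamini-Hochberg value.
    """

    set_name: str
    N: int
    D: int
    n: int
    k: int
    p_point: float
    p_tail: float
    q: float | None = None


@dataclass
class TrajectoryStat:
    probe: str
    volatility: float
    linear_trend: float
    units: str = "log2"


def _check_bounds(N: int, D: int, n: int, k: int) -> None:
    if min(N, D, n, k) < 0:
        raise ValueError("N, D, n, k must be non-negative")
    if D > N or n > N:
        raise ValueError(f"D={D} and n={n} must not exceed N={N}")
    if k > min(n, D):
        raise ValueError(f"k={k} exceeds min(n={n}, D={D})")
    if n - k > N - D:
        raise ValueError(f"n-k={n - k} exceeds N-D={N - D}")


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_point(N: int, D: int, n: int, k: int) -> float:
    """Probability of drawing exactly ``k`` set members in ``n`` of ``N`` draws."""
    _check_bounds(N, D, n, k)
    if N <= _EXACT_N_LIMIT:
        return float(
            Fraction(math.comb(D, k) * math.comb(N - D, n - k), math.comb(N, n))
        )
    return math.exp(
        _log_comb(D, k) + _log_comb(N - D, n - k) - _log_comb(N, n)
    )


def hypergeom_tail(N: int, D: int, n: int, k: int) -> float:
    """Upper-tail p-value ``P[X >= k]`` under the hypergeometric null."""
    _check_bounds(N, D, n, k)
    k_max = min(n, D)
    if N <= _EXACT_N_LIMIT:
        numerator = sum(
            math.comb(D, j) * math.comb(N - D, n - j)
            for j in range(k, k_max + 1)
            if n - j <= N - D
        )
        return float(Fraction(numerator, math.comb(N, n)))
    total = 0.0
    for j in range(k, k_max + 1):
        if n - j > N - D:
            continue
        total += math.exp(_log_comb(D, j) + _log_comb(N - D, n - j) - _log_comb(N, n))
    return min(total, 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Step-up BH adjusted values, monotone and capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def enrich(
    selected: Iterable[str],
    annotation: AnnotationSet,
    universe: Iterable[str],
    mode: str = "tail",
    adjust: str = "none",
) -> tuple[list[EnrichmentResult], list[str]]:
    """Score every pathway and label against a selected probe set.

    Returns results sorted ascending by the chosen p (ties broken by set
    name) plus notes for sets skipped because they have no probes in the
    universe (D = 0).
    """
    if mode not in ("point", "tail"):
        raise ValueError("mode must be 'point' or 'tail'")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    universe_set = set(universe)
    selected_set = set(selected)
    stray = selected_set - universe_set
    if stray:
        raise ValueError(
            f"selected probes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe_set), len(selected_set)
    results: list[EnrichmentResult] = []
    notes: list[str] = []
    for name, members in sorted(annotation.named_sets().items()):
        in_universe = set(members) & universe_set
        D = len(in_universe)
        if D == 0:
            notes.append(f"set '{name}' skipped: no probes in the universe (D=0)")
            continue
        k = len(selected_set & in_universe)
        results.append(
            EnrichmentResult(
                set_name=name,
                N=N,
                D=D,
                n=n,
                k=k,
                p_point=hypergeom_point(N, D, n, k),
                p_tail=hypergeom_tail(N, D, n, k),
            )
        )
    keyfn = (lambda r: (r.p_point, r.set_name)) if mode == "point" else (
        lambda r: (r.p_tail, r.set_name)
    )
    results.sort(key=keyfn)
    if adjust == "BH" and results:
        ps = [r.p_tail if mode == "tail" else r.p_point for r in results]
        for r, q in zip(results, benjamini_hochberg(ps)):
            r.q = q
    return results, notes


def precision_recall(
    selected: Iterable[str], reference: Iterable[str]
) -> tuple[float | None, float | None]:
    """``(|S∩R|/|S|, |S∩R|/|R|)``; ``None`` where the denominator is empty."""
    S, R = set(selected), set(reference)
    common = len(S & R)
    precision = common / len(S) if S else None
    recall = common / len(R) if R else None
    return precision, recall


def volatility(values: Sequence[float]) -> float:
    """Sum of absolute successive differences of a trajectory."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("volatility needs at least 2 values")
    return float(np.abs(np.diff(arr)).sum())


def linear_trend(values: Sequence[float]) -> float:
    """Sum of successive differences; telescopes to last minus first."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("linear trend needs at least 2 values")
    return float(np.diff(arr).sum())


def rank_by_volatility(
    data: AggregatedDataset | DiscretizedTrajectorySet,
    descending: bool = True,
) -> list[TrajectoryStat]:
    """Score every probe's volatility and trend and sort by volatility.

    Accepts either raw aggregated profiles (log2 units) or discretized bin
    sequences (bin units); the units are recorded on each row.  Ties break
    by probe ID ascending.
    """
    if isinstance(data, AggregatedDataset):
        rows, probes, units = data.values, data.probe_ids, "log2"
    else:
        rows, probes, units = data.trajectories, data.probe_ids, "bins"
    if rows.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    stats = [
        TrajectoryStat(
            probe=p,
            volatility=volatility(row),
            linear_trend=linear_trend(row),
            units=units,
        )
        for p, row in zip(probes, rows)
    ]
    sign = -1.0 if descending else 1.0
    stats.sort(key=lambda s: (sign * s.volatility, s.probe))
    return stats


def pathway_intersection(
    context: Iterable[str], annotation: AnnotationSet
) -> dict[str, tuple[int, int, int]]:
    """Per pathway: (|context|, |pathway|, |context ∩ pathway|)."""
    context_set = set(context)
    return {
        name: (len(context_set), len(members), len(context_set & set(members)))
        for name, members in sorted(annotation.pathways.items())
    }
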