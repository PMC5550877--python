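"""Fisher's exact term enrichment with Benjamini-Hochberg FDR.

Enrichment is one-sided (over-representation): for a term annotating K of N
universe genes of which k fall in the n-gene query set, the P value is the
hypergeometric upper tail ``P(X >= k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "AnnotationMap",
    "EnrichmentResult",
    "CandidateSelection",
    "bh_fdr",
    "fisher_enrichment",
    "select_focus_candidates",
]


@dataclass(frozen=True)
class AnnotationMap:
    """Term id -> (term name, gene set), plus the testable gene universe."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise InputError(f"term {tid!r} has an empty gene set")
            stray = genes - self.universe
            if stray:
                raise InputError(
                    f"term {tid!r} annotates genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        try:
            return self.terms[term_id][1]
        except KeyError:
            raise InputError(f"unknown term id {term_id!r}") from None

    def name(self, term_id: str) -> str:
        try:
            return self.terms[term_id][0]
        except KeyError:
            raise InputError(f"unknown term id {term_id!r}") from None


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in term
    K: int  # term size within universe
    n: int  # query set size
    N: int  # universe size
    p_value: float
    q_value: float


@dataclass(frozen=True)
class CandidateSelection:
    candidates: Mapping[str, tuple[str, ...]]  # perturbation label -> sorted genes
    focus_terms: tuple[str, ...]
    overlap: tuple[str, ...]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted order, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_p_enrichment(k: int, K: int, n: int, N: int) -> float:
    """One-sided (greater) Fisher exact P for the 2x2 overlap table.

    Equivalent to the hypergeometric upper tail ``P(X >= k)`` with the
    table margins fixed at (K, N-K) x (n, N-n).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(f"inconsistent table cells k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    de_genes: Iterable[str], annotations: AnnotationMap
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation of `de_genes`.

    Results are sorted by ascending P value, ties broken by term id.
    """
    de = set(de_genes)
    stray = de - annotations.universe
    if stray:
        raise InputError(
            f"query genes outside the annotation universe: {sorted(stray)}"
        )
    if not annotations.universe:
        raise InputError("annotation universe is empty")
    N = len(annotations.universe)
    n = len(de)
    term_ids = annotations.term_ids
    rows = []
    for tid in term_ids:
        genes = annotations.genes(tid)
        K = len(genes)
        k = len(genes & de)
        rows.append((tid, k, K, fisher_p_enrichment(k, K, n, N)))
    q = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=annotations.name(tid),
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=float(qv),
        )
        for (tid, k, K, p), qv in zip(rows, q)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def select_focus_candidates(
    enrichments: Mapping[str, Sequence[EnrichmentResult]],
    de_sets: Mapping[str, Iterable[str]],
    focus_terms: Sequence[str],
    annotations: AnnotationMap,
) -> CandidateSelection:
    """Per-perturbation focus-term candidates and their cross overlap.

    For each perturbation, candidates are the union over `focus_terms` of
    (term genes intersected with that perturbation's DE set); the overlap is
    the intersection of the per-perturbation candidate lists.  `enrichments`
    fixes the set of perturbation labels considered and must cover `de_sets`.
    """
    unknown = [t for t in focus_terms if t not in annotations.terms]
    if unknown:
        raise InputError(f"unknown focus terms: {unknown}")
    labels = list(enrichments)
    missing = [lab for lab in labels if lab not in de_sets]
    if missing:
        raise InputError(f"no DE set for perturbation(s): {missing}")
    candidates: dict[str, tuple[str, ...]] = {}
    for lab in labels:
        de = set(de_sets[lab])
        picked: set[str] = set()
        for tid in focus_terms:
            picked |= annotations.genes(tid) & de
        candidates[lab] = tuple(sorted(picked))
    if labels:
        overlap_set = set(candidates[labels[0]])
        for lab in labels[1:]:
            overlap_set &= set(candidates[lab])
    else:
        overlap_set = set()
    return CandidateSelection(
        candidates=candidates,
        focus_terms=tuple(focus_terms),
        overlap=tuple(sorted(overlap_set)),
    )
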