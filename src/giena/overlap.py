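"""Hypergeometric overlap between dysregulated pairs and physical interactions.

Do the statistically dysregulated pairs coincide with physical
protein-protein interactions more often than chance?  The draw is modelled
as an urn: out of N testable gene pairs (pairs within a tested pathway
whose two genes both have at least one physical interaction on record),
m are physical interactions; n dysregulated pairs are "drawn" and k of
them turn out physical.  The upper tail

    P(X >= k) = sum_{i=k}^{min(n,m)} C(m, i) C(N-m, n-i) / C(N, n)

is reported without multiple-testing correction (a single test per
dataset).

Two population conventions are provided.  ``literal`` sums the per-pathway
pair counts, N = sum_i C(a_i, 2) with a_i the number of covered genes in
pathway i, so pairs shared by several pathways are counted once per
pathway (and m is summed per pathway the same way, keeping the urn
coherent).  ``dedup`` counts each distinct pair once throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .io import GeneSetCollection, PhysicalInteractionNetwork

__all__ = ["OverlapTest", "overlap_parameters", "hypergeom_upper_tail", "run_overlap"]


@dataclass
class OverlapTest:
    """Urn parameters and p-value of the physical-overlap test."""

    N: int
    n: int
    m: int
    k: int
    mode: str = "literal"
    p_value: float | None = None
    applicable: bool = True

    def validate(self) -> None:
        if not self.applicable:
            return
        if not (0 <= self.k <= min(self.n, self.m) and self.n <= self.N and self.m <= self.N):
            raise ValidationError(
                f"incoherent urn parameters N={self.N}, n={self.n}, "
                f"m={self.m}, k={self.k}"
            )


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, n: int, m: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, m, n), in log-gamma space.

    Evaluated as a log-sum-exp over the support so that populations up to
    ~1e6 pairs do not overflow.
    """
    for name, v in (("N", N), ("n", n), ("m", m), ("k", k)):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v}")
    N, n, m, k = int(N), int(n), int(m), int(k)
    if n > N or m > N:
        raise ValidationError(f"need n <= N and m <= N, got N={N}, n={n}, m={m}")
    hi = min(n, m)
    lo = max(k, max(0, n - (N - m)))
    if k > hi:
        raise ValidationError(f"k={k} exceeds min(n, m)={hi}")
    if lo > hi:
        return 0.0
    if k <= max(0, n - (N - m)):
        return 1.0
    i = np.arange(lo, hi + 1)
    log_terms = _log_comb(m, i) + _log_comb(N - m, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def overlap_parameters(
    pathways_tested: GeneSetCollection,
    sig_edges,
    ppi: PhysicalInteractionNetwork,
    mode: str = "literal",
) -> OverlapTest:
    """Build the urn from tested pathways, significant pairs and the PPI.

    ``pathways_tested`` must be restricted to pathways that were actually
    scored.  ``sig_edges`` is any iterable of objects (or 2-tuples) naming
    the two genes of each significantly dysregulated pair.
    """
    if mode not in ("literal", "dedup"):
        raise ValidationError(f"unknown overlap mode {mode!r}")

    def _pair(e):
        if hasattr(e, "gene_i"):
            a, b = e.gene_i, e.gene_j
        else:
            a, b = e
        a, b = a.upper(), b.upper()
        return (a, b) if a < b else (b, a)

    sig_pairs = {_pair(e) for e in sig_edges}

    N = 0
    m = 0
    universe: set[tuple[str, str]] = set()
    for _, members in pathways_tested.items():
        covered = sorted(g for g in members if ppi.covered(g))
        N += comb(len(covered), 2)
        pathway_pairs = list(combinations(covered, 2))
        m += sum(1 for a, b in pathway_pairs if ppi.has_edge(a, b))
        universe.update(pathway_pairs)

    if mode == "dedup":
        N = len(universe)
        m = sum(1 for a, b in universe if ppi.has_edge(a, b))

    eligible = {p for p in sig_pairs if p in universe}
    n = len(eligible)
    k = sum(1 for a, b in eligible if ppi.has_edge(a, b))

    test = OverlapTest(N=N, n=n, m=m, k=k, mode=mode)
    if N == 0:
        test.applicable = False
        return test
    test.validate()
    return test


def run_overlap(
    pathways_tested: GeneSetCollection,
    sig_edges,
    ppi: PhysicalInteractionNetwork,
    mode: str = "literal",
) -> OverlapTest:
    """Urn construction plus the upper-tail p-value in one call."""
    test = overlap_parameters(pathways_tested, sig_edges, ppi, mode)
    if test.applicable:
        test.p_value = hypergeom_upper_tail(test.N, test.n, test.m, test.k)
    return test
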