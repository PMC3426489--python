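from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from giena import (
    GeneSetCollection,
    PhysicalInteractionNetwork,
    ValidationError,
    hypergeom_upper_tail,
    overlap_parameters,
    run_overlap,
)


def enumerate_upper_tail(N, n, m, k):
    """Exhaustive draw enumeration: fraction of n-subsets with >= k successes."""
    hits = 0
    total = 0
    population = list(range(N))
    successes = set(range(m))
    for draw in combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def test_upper_tail_examples():
    assert hypergeom_upper_tail(10, 3, 4, 0) == 1.0
    assert hypergeom_upper_tail(10, 3, 4, 3) == pytest.approx(4 / 120)  # C(4,3)/C(10,3)


def test_upper_tail_matches_enumeration_small():
    rng = np.random.default_rng(0)
    for _ in range(30):
        N = int(rng.integers(2, 9))
        n = int(rng.integers(1, N + 1))
        m = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(n, m) + 1))
        assert hypergeom_upper_tail(N, n, m, k) == pytest.approx(
            enumerate_upper_tail(N, n, m, k), abs=1e-12
        )


def test_upper_tail_matches_scipy_and_logspace_scale():
    # independent implementation cross-check, incl. a large population
    for N, n, m, k in [(100, 20, 30, 10), (10_000, 200, 500, 20), (1_000_000, 1000, 2000, 10)]:
        ref = stats.hypergeom.sf(k - 1, N, m, n)
        assert hypergeom_upper_tail(N, n, m, k) == pytest.approx(ref, rel=1e-9)
        assert np.isfinite(hypergeom_upper_tail(N, n, m, k))


def test_upper_tail_monotone_in_k_and_sums_to_one():
    N, n, m = 40, 12, 15
    tails = [hypergeom_upper_tail(N, n, m, k) for k in range(min(n, m) + 1)]
    assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
    pmf_total = sum(
        hypergeom_upper_tail(N, n, m, k)
        - (hypergeom_upper_tail(N, n, m, k + 1) if k < min(n, m) else 0.0)
        for k in range(min(n, m) + 1)
    )
    assert pmf_total == pytest.approx(1.0, abs=1e-12)


def test_upper_tail_validates_parameters():
    with pytest.raises(ValidationError):
        hypergeom_upper_tail(10, 11, 4, 0)
    with pytest.raises(ValidationError):
        hypergeom_upper_tail(10, 3, 4, 4)  # k > min(n, m)
    with pytest.raises(ValidationError):
        hypergeom_upper_tail(10, 3, -1, 0)


def test_urn_parameters_single_pathway():
    gsc = GeneSetCollection({"P": ("d", frozenset({"A", "B", "C"}))})
    ppi = PhysicalInteractionNetwork({("A", "B"), ("A", "C"), ("B", "C"),
                                      ("A", "X")})  # all of A, B, C covered
    ppi_small = PhysicalInteractionNetwork({("A", "B"), ("C", "X")})
    t = overlap_parameters(gsc, [("A", "B"), ("A", "C")], ppi_small)
    assert (t.N, t.m) == (3, 1)  # C(3,2) pairs; only A-B is physical
    assert (t.n, t.k) == (2, 1)


def test_urn_modes_differ_on_shared_pairs():
    gsc = GeneSetCollection({
        "P1": ("d", frozenset({"A", "B", "C"})),
        "P2": ("d", frozenset({"A", "B", "D"})),
    })
    ppi = PhysicalInteractionNetwork(
        {("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")}
    )
    lit = overlap_parameters(gsc, [], ppi, mode="literal")
    ded = overlap_parameters(gsc, [], ppi, mode="dedup")
    assert lit.N == 6  # C(3,2) + C(3,2): pair A-B counted twice
    assert ded.N == 5  # distinct pairs
    assert lit.m == 6 and ded.m == 5


def bruteforce_parameters(pathways, sig_pairs, ppi_edges, mode):
    covered = {g for e in ppi_edges for g in e}
    ppi = {tuple(sorted(e)) for e in ppi_edges}
    universe = set()
    N = m = 0
    for members in pathways.values():
        cov = sorted(g for g in members if g in covered)
        pairs = [tuple(sorted(p)) for p in combinations(cov, 2)]
        N += comb(len(cov), 2)
        m += sum(p in ppi for p in pairs)
        universe |= set(pairs)
    if mode == "dedup":
        N = len(universe)
        m = sum(p in ppi for p in universe)
    sig = {tuple(sorted(p)) for p in sig_pairs} & universe
    return N, len(sig), m, sum(p in ppi for p in sig)


@pytest.mark.parametrize("mode", ["literal", "dedup"])
def test_urn_parameters_match_bruteforce(mode):
    rng = np.random.default_rng(23)
    genes = [f"G{i}" for i in range(15)]
    for _ in range(20):
        pathways = {
            f"P{j}": frozenset(rng.choice(genes, size=rng.integers(3, 7), replace=False))
            for j in range(4)
        }
        gsc = GeneSetCollection({k: ("d", v) for k, v in pathways.items()})
        ppi_edges = {
            tuple(sorted((genes[i], genes[j])))
            for i, j in rng.integers(0, 15, size=(20, 2)) if i != j
        }
        ppi = PhysicalInteractionNetwork(set(ppi_edges))
        all_pairs = [p for mem in pathways.values() for p in combinations(sorted(mem), 2)]
        sig = [all_pairs[i] for i in rng.choice(len(all_pairs),
                                                size=min(8, len(all_pairs)), replace=False)]
        t = run_overlap(gsc, sig, ppi, mode=mode)
        ref = bruteforce_parameters(pathways, sig, ppi_edges, mode)
        assert (t.N, t.n, t.m, t.k) == ref
        if t.applicable:
            assert 0 <= t.p_value <= 1
            assert t.k <= min(t.n, t.m) and t.n <= t.N and t.m <= t.N


def test_empty_population_not_applicable():
    gsc = GeneSetCollection({"P": ("d", frozenset({"A", "B"}))})
    ppi = PhysicalInteractionNetwork({("X", "Y")})  # no pathway gene covered
    t = run_overlap(gsc, [], ppi)
    assert not t.applicable and t.p_value is None
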