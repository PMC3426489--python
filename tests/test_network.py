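import numpy as np
import pandas as pd
import pytest
from scipy import stats

from giena import (
    PhysicalInteractionNetwork,
    ProfileKind,
    build_network,
    gene_level_de,
    hub_report,
    significant_pairs,
)
from giena.network import DysregulationNetwork, InteractionEdge

K = ProfileKind


def _edge(a, b, pathways, kinds=(K.COOPERATION,), p=0.01):
    return InteractionEdge(a, b, set(kinds), {k: p for k in kinds}, set(pathways))


def test_identical_distributions_excluded(tiny_dataset):
    ds = tiny_dataset
    ds.values[0] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # same in both classes
    ds.values[1] = np.tile([4.0, 3.0, 2.0, 1.0], 2)
    edges = significant_pairs(ds, {"GA", "GB"}, [K.COOPERATION], alpha=0.05)
    assert edges == []


def test_pair_pvalues_match_reference_ttest(tiny_dataset):
    ds = tiny_dataset
    edges = significant_pairs(ds, set(ds.genes), None, alpha=1.0, pathway="P")
    assert len(edges) == 6  # alpha=1 keeps every pair
    for e in edges:
        i, j = ds.gene_index[e.gene_i], ds.gene_index[e.gene_j]
        for kind, p in e.p_by_kind.items():
            from giena.profiles import compute_profile

            prof = compute_profile(ds.values[i], ds.values[j], kind)
            ref = stats.ttest_ind(prof[ds.case_mask], prof[~ds.case_mask],
                                  equal_var=True).pvalue
            assert p == pytest.approx(ref, abs=1e-10)


def test_injected_pair_detected_strongly(signal_dataset):
    ds, gsc, truth = signal_dataset
    edges = significant_pairs(ds, gsc.genes("PW001"), [K.COOPERATION],
                              alpha=0.001, pathway="PW001")
    found = {e.pair for e in edges}
    assert truth.injected_pairs("PW001") <= found


def test_gene_level_de_constant_gene(tiny_dataset):
    ds = tiny_dataset
    ds.values[2] = 1.0
    de = gene_level_de(ds)
    row = de[de["gene"] == "GC"].iloc[0]
    assert row["p"] == 1.0 and row["constant"]
    assert row["q"] == 1.0


def test_gene_level_de_finds_shifted_gene():
    from giena import ExpressionDataset

    rng = np.random.default_rng(0)
    values = rng.normal(size=(200, 20))
    values[57, 10:] += 3.0  # strong case shift
    ds = ExpressionDataset(
        genes=[f"G{i:03d}" for i in range(200)],
        samples=[f"s{i}" for i in range(20)],
        values=values,
        labels=np.array(["control"] * 10 + ["case"] * 10, dtype=object),
    )
    de = gene_level_de(ds)
    assert de.loc[de["q"].idxmin(), "gene"] == "G057"


def test_build_network_filter_semantics():
    """DE node removal takes its edges; singleton filtering prunes the rest."""
    edges = [_edge("A", "B", {"P1"}), _edge("B", "C", {"P1"})]
    de_q = {"A": 0.001, "B": 0.5, "C": 0.9}
    net = build_network(edges, de_q, None, de_q_threshold=0.01,
                       drop_de_nodes=True, drop_singletons=True)
    assert set(net.nodes) == {"B", "C"}
    assert [e.pair for e in net.edges] == [("B", "C")]
    # without singleton filtering the orphaned endpoint stays, degree 0
    net2 = build_network(edges, de_q, None, de_q_threshold=0.01,
                        drop_de_nodes=True, drop_singletons=False)
    assert set(net2.nodes) == {"B", "C"}  # A itself was DE-removed
    edges3 = [_edge("A", "B", {"P1"})]
    net3 = build_network(edges3, {"B": 0.001}, None, drop_de_nodes=True,
                        drop_singletons=False)
    assert set(net3.nodes) == {"A"} and net3.nodes["A"].degree == 0


def test_cross_pathway_flag_and_degree():
    edges = [_edge("X", "A", {"P1"}), _edge("X", "B", {"P2"}), _edge("X", "C", {"P3"})]
    net = build_network(edges, None, None, drop_de_nodes=False)
    assert net.nodes["X"].degree == 3 and net.nodes["X"].cross_pathway
    assert not net.nodes["A"].cross_pathway


def test_multi_kind_pair_is_single_edge():
    edges = [
        _edge("A", "B", {"P1"}, kinds=(K.COOPERATION,), p=0.01),
        _edge("A", "B", {"P2"}, kinds=(K.DEPENDENCY,), p=0.03),
    ]
    net = build_network(edges, None, None, drop_de_nodes=False)
    assert net.n_edges == 1
    e = net.edges[0]
    assert e.kinds == {K.COOPERATION, K.DEPENDENCY}
    assert e.pathways == {"P1", "P2"}


def test_physical_flags_are_ppi_intersection():
    ppi = PhysicalInteractionNetwork({("A", "B")})
    edges = [_edge("A", "B", {"P"}), _edge("B", "C", {"P"})]
    net = build_network(edges, None, ppi, drop_de_nodes=False)
    flags = {e.pair: e.physical for e in net.edges}
    assert flags == {("A", "B"): True, ("B", "C"): False}


def test_hub_report_star_and_ties():
    edges = [_edge("HUB", leaf, {"P"}) for leaf in ["A", "B", "C", "D"]]
    net = build_network(edges, None, None, drop_de_nodes=False)
    report = hub_report(net)
    assert report.iloc[0]["gene"] == "HUB" and report.iloc[0]["degree"] == 4
    # leaves tie at degree 1, broken lexicographically
    assert list(report["gene"][1:]) == ["A", "B", "C", "D"]
    assert hub_report(DysregulationNetwork.from_edges([])).empty


def bruteforce_network(edge_list, de_q, de_thr, drop_de, drop_singletons):
    """Set-algebra reference for build_network's node/edge bookkeeping."""
    merged = {}
    for a, b, pw in edge_list:
        key = tuple(sorted((a, b)))
        merged.setdefault(key, set()).add(pw)
    bad = {g for g, q in de_q.items() if q < de_thr} if drop_de else set()
    kept = {e: pws for e, pws in merged.items() if not (set(e) & bad)}
    nodes = {g for e in kept for g in e}
    if not drop_singletons:
        nodes |= {g for e in merged for g in e} - bad
    degree = {g: sum(g in e for e in kept) for g in nodes}
    cross = {g: len({pw for e, pws in kept.items() if g in e for pw in pws}) >= 2
             for g in nodes}
    return kept, nodes, degree, cross


@pytest.mark.parametrize("drop_de,drop_singletons", [(True, True), (True, False), (False, True)])
def test_build_network_matches_set_algebra(drop_de, drop_singletons):
    rng = np.random.default_rng(17)
    genes = [f"G{i}" for i in range(12)]
    for _ in range(25):
        raw = [
            (genes[i], genes[j], f"P{rng.integers(3)}")
            for i, j in rng.integers(0, 12, size=(15, 2)) if i != j
        ]
        de_q = {g: float(rng.uniform()) for g in genes}
        edges = [_edge(a, b, {pw}) for a, b, pw in raw]
        net = build_network(edges, de_q, None, de_q_threshold=0.3,
                           drop_de_nodes=drop_de, drop_singletons=drop_singletons)
        kept, nodes, degree, cross = bruteforce_network(
            raw, de_q, 0.3, drop_de, drop_singletons)
        assert {e.pair for e in net.edges} == set(kept)
        assert set(net.nodes) == nodes
        for g in nodes:
            assert net.nodes[g].degree == degree[g]
            assert net.nodes[g].cross_pathway == cross[g]


def test_every_reported_edge_below_alpha(signal_dataset):
    ds, gsc, _ = signal_dataset
    alpha = 0.05
    edges = significant_pairs(ds, gsc.genes("PW001"), None, alpha, pathway="PW001")
    assert edges  # injected pathway yields pairs
    for e in edges:
        assert e.kinds and all(p < alpha for p in e.p_by_kind.values())
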