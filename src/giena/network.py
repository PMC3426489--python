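"""Dysregulation-network construction from significant pathways.

Within each pathway called dysregulated, every gene pair is re-tested
individually: a two-sided t-test on the interaction profile at a loose,
uncorrected threshold (default p < 0.05).  The significant pairs from all
pathways are merged into one undirected network whose edges carry the
profile kinds that flagged them, the contributing pathways and the pair
p-values.  Two optional filters reproduce the published network views:
removal of genes that are differentially expressed on their own
(q < 0.01), so the network shows what pair-level analysis adds beyond
single-gene analysis, and removal of the resulting singletons.  Nodes whose
surviving edges span two or more pathways are flagged as cross-pathway
hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import qvalues, significant_pathways
from .errors import ValidationError
from .io import ExpressionDataset, GeneSetCollection, PhysicalInteractionNetwork
from .profiles import ProfileKind, profile_matrix, two_sample_t

__all__ = [
    "InteractionEdge",
    "NodeInfo",
    "DysregulationNetwork",
    "significant_pairs",
    "gene_level_de",
    "build_network",
    "collect_significant_pairs",
    "hub_report",
]


@dataclass
class InteractionEdge:
    """A significantly dysregulated gene pair (undirected)."""

    gene_i: str
    gene_j: str
    kinds: set[ProfileKind]
    p_by_kind: dict[ProfileKind, float]
    pathways: set[str]
    physical: bool = False

    def __post_init__(self) -> None:
        if self.gene_i == self.gene_j:
            raise ValidationError(f"self-edge {self.gene_i}")
        if self.gene_i > self.gene_j:
            self.gene_i, self.gene_j = self.gene_j, self.gene_i

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)


@dataclass
class NodeInfo:
    pathways: set[str] = field(default_factory=set)
    degree: int = 0
    cross_pathway: bool = False
    de_q: float | None = None


@dataclass
class DysregulationNetwork:
    """Graph of dysregulated pairs with per-node annotations."""

    nodes: dict[str, NodeInfo]
    edges: list[InteractionEdge]

    @classmethod
    def from_edges(cls, edges: list[InteractionEdge]) -> "DysregulationNetwork":
        nodes: dict[str, NodeInfo] = {}
        for e in edges:
            for g in e.pair:
                info = nodes.setdefault(g, NodeInfo())
                info.degree += 1
                info.pathways |= e.pathways
        for g, info in nodes.items():
            pw = set()
            for e in edges:
                if g in e.pair:
                    pw |= e.pathways
            info.cross_pathway = len(pw) >= 2
        return cls(nodes=nodes, edges=sorted(edges, key=lambda e: e.pair))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        from .io import _net_to_nx

        return _net_to_nx(self)


def significant_pairs(
    ds: ExpressionDataset,
    pathway_genes,
    kinds=None,
    alpha: float = 0.05,
    *,
    pathway: str = "",
    equal_var: bool = True,
) -> list[InteractionEdge]:
    """Individually dysregulated pairs of one pathway.

    Each pair is tested per profile kind with a two-sided t-test
    (df = n_case + n_control - 2 for the pooled form) and kept for a kind
    iff p < alpha -- deliberately loose and uncorrected, since the pathway
    as a whole has already passed the enrichment test.  Pairs flagged by
    several kinds become a single edge with merged annotations.
    """
    if kinds is None:
        kinds = list(ProfileKind)
    kinds = [ProfileKind.coerce(k) for k in kinds]
    genes = sorted(set(g.upper() for g in pathway_genes) & set(ds.genes))
    if len(genes) < 2:
        raise ValidationError(f"pathway matches {len(genes)} gene(s); need >= 2")
    idx = [ds.gene_index[g] for g in genes]
    X = ds.values[idx]
    m = len(ds.samples)
    df_t = m - 2 if equal_var else None

    found: dict[tuple[str, str], InteractionEdge] = {}
    for kind in kinds:
        V, ii, jj = profile_matrix(X, kind)
        t = two_sample_t(V, ds.case_mask, equal_var=equal_var)
        if equal_var:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_t)
        else:  # Welch df per pair
            p = np.empty_like(t)
            y = ds.case_mask
            for r in range(V.shape[0]):
                p[r] = stats.ttest_ind(V[r, y], V[r, ~y], equal_var=False).pvalue
        # constant profiles have t = 0 -> p = 1, never significant
        for r in np.nonzero(p < alpha)[0]:
            a, b = genes[ii[r]], genes[jj[r]]
            e = found.setdefault(
                (a, b),
                InteractionEdge(gene_i=a, gene_j=b, kinds=set(), p_by_kind={},
                                pathways={pathway} if pathway else set()),
            )
            e.kinds.add(kind)
            e.p_by_kind[kind] = float(p[r])
    return [found[k] for k in sorted(found)]


def gene_level_de(ds: ExpressionDataset, *, equal_var: bool = True) -> pd.DataFrame:
    """Per-gene differential expression: t, two-sided p, Storey q.

    Constant genes get t = 0 and p = 1 (flagged). q-values use the same
    Storey machinery as the pathway results (BH fallback for short lists).
    """
    t = two_sample_t(ds.values, ds.case_mask, equal_var=equal_var)
    m = len(ds.samples)
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    y = ds.case_mask
    const = (np.ptp(ds.values[:, y], axis=1) == 0.0) & (
        np.ptp(ds.values[:, ~y], axis=1) == 0.0
    )
    p = np.where(const, 1.0, p)
    q = qvalues(p)
    return pd.DataFrame(
        {"gene": ds.genes, "t": t, "p": p, "q": q, "constant": const}
    )


def build_network(
    edges: list[InteractionEdge],
    de_q: pd.DataFrame | dict | None = None,
    ppi: PhysicalInteractionNetwork | None = None,
    de_q_threshold: float = 0.01,
    drop_de_nodes: bool = True,
    drop_singletons: bool = True,
) -> DysregulationNetwork:
    """Merge pathway edge lists into one filtered, annotated network.

    Filters, in order: (1) if ``drop_de_nodes``, genes differentially
    expressed at q < ``de_q_threshold`` are removed along with their
    incident edges; (2) if ``drop_singletons``, nodes left without any
    edge are removed.  Each surviving edge is marked ``physical`` iff the
    pair is present in ``ppi``.
    """
    if isinstance(de_q, pd.DataFrame):
        de_map = dict(zip(de_q["gene"], de_q["q"]))
    else:
        de_map = dict(de_q) if de_q else {}

    # merge duplicate pairs arising from different pathways
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for e in edges:
        prev = merged.get(e.pair)
        if prev is None:
            merged[e.pair] = InteractionEdge(
                gene_i=e.gene_i, gene_j=e.gene_j, kinds=set(e.kinds),
                p_by_kind=dict(e.p_by_kind), pathways=set(e.pathways),
            )
        else:
            prev.kinds |= e.kinds
            prev.pathways |= e.pathways
            for k, pv in e.p_by_kind.items():
                prev.p_by_kind[k] = min(pv, prev.p_by_kind.get(k, 1.0))

    kept = list(merged.values())
    universe = {g for e in kept for g in e.pair}
    if drop_de_nodes and de_map:
        bad = {g for g, q in de_map.items() if q < de_q_threshold}
        kept = [e for e in kept if e.gene_i not in bad and e.gene_j not in bad]
        universe -= bad

    if ppi is not None:
        for e in kept:
            e.physical = ppi.has_edge(e.gene_i, e.gene_j)

    net = DysregulationNetwork.from_edges(kept)
    if not drop_singletons:
        # keep nodes whose every pair was filtered away as degree-0 nodes
        for g in sorted(universe - set(net.nodes)):
            net.nodes[g] = NodeInfo()
    for g, info in net.nodes.items():
        if g in de_map:
            info.de_q = float(de_map[g])
    return net


def collect_significant_pairs(
    ds: ExpressionDataset,
    gsc: GeneSetCollection,
    results: pd.DataFrame,
    alpha: float = 0.05,
    q_threshold: float = 0.01,
    *,
    all_pathways: bool = False,
    equal_var: bool = True,
) -> list[InteractionEdge]:
    """Pair-test every dysregulated (pathway, kind) and pool the edges.

    By default only pathways significant at ``q_threshold`` contribute,
    each tested under the kind(s) for which it was significant;
    ``all_pathways`` lifts the gate for exploratory use.
    """
    if all_pathways:
        selected = results[["pathway", "kind"]]
    else:
        selected = significant_pathways(results, q_threshold)[["pathway", "kind"]]
    edges: list[InteractionEdge] = []
    for pathway, group in selected.groupby("pathway", sort=True):
        kinds = [ProfileKind.coerce(k) for k in sorted(group["kind"])]
        edges.extend(
            significant_pairs(
                ds, gsc.genes(pathway), kinds, alpha,
                pathway=pathway, equal_var=equal_var,
            )
        )
    return edges


def hub_report(net: DysregulationNetwork, top: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree (ties broken lexicographically)."""
    rows = [
        {
            "gene": g,
            "degree": info.degree,
            "n_pathways": len(info.pathways),
            "cross_pathway": info.cross_pathway,
        }
        for g, info in net.nodes.items()
    ]
    if not rows:
        return pd.DataFrame(columns=["gene", "degree", "n_pathways", "cross_pathway"])
    df = pd.DataFrame(rows).sort_values(
        ["degree", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(top) if top is not None else df
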