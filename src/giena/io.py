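"""Readers and writers for every external format the pipeline touches.

Expression matrices arrive as plain TSV (first column = gene symbol,
header row = sample identifiers) or GCT 1.2; phenotype labels as CLS or a
two-column sample/class TSV; gene sets in the MSigDB GMT dialect; physical
protein interactions as a two-column symbol TSV.  Dysregulation networks
are written as SIF, GraphML or node/edge TSV tables (Cytoscape-friendly).

All gene symbols are upper-cased on ingest: the pipeline joins expression,
gene sets and the protein-interaction network by symbol, and the human
reference resources use upper-case symbols.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: class names treated as the control/reference class when a labels file
#: uses recognisable names; otherwise the first class listed is control.
_CONTROL_SYNONYMS = {"control", "ctrl", "normal", "healthy", "wt", "wildtype", "wild-type", "reference"}
_CASE_SYNONYMS = {"case", "disease", "tumor", "tumour", "cancer", "mut", "mutant", "treated"}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Normalized gene x sample expression matrix with two-class labels.

    ``labels[j]`` is ``"case"`` or ``"control"`` for sample ``samples[j]``.
    Values are expected to be already normalized and probe-collapsed;
    nothing here re-scales them.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    labels: np.ndarray
    gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.validate()
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    def validate(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene symbols: {dupes[:10]}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"labels must be case/control, got {sorted(bad)}")
        n_case = int((self.labels == CASE).sum())
        n_control = len(self.labels) - n_case
        if n_case < 2 or n_control < 2:
            raise ValidationError(
                f"need >= 2 samples per class, got {n_case} case / "
                f"{n_control} control"
            )

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == CASE

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return len(self.samples) - self.n_case


@dataclass
class GeneSetCollection:
    """Named pathways, each a (description, frozenset-of-symbols) pair."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def items(self):
        for name, (_, members) in self.sets.items():
            yield name, members

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


@dataclass
class PhysicalInteractionNetwork:
    """Undirected physical protein-interaction edge set (no self-loops)."""

    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        clean = set()
        for a, b in self.edges:
            a, b = a.upper(), b.upper()
            if a == b:
                raise ValidationError(f"self-loop {a}-{b} in interaction network")
            clean.add((a, b) if a < b else (b, a))
        self.edges = clean
        self._covered = {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        a, b = a.upper(), b.upper()
        return ((a, b) if a < b else (b, a)) in self.edges

    def covered(self, gene: str) -> bool:
        """True iff the gene has at least one physical interaction."""
        return gene.upper() in self._covered

    @property
    def nodes(self) -> set[str]:
        return set(self._covered)


# ---------------------------------------------------------------------------
# expression + labels
# ---------------------------------------------------------------------------

def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ParseError(f"{path}: line 1: empty header row")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[1] == 0:
        raise ParseError(f"{path}: line 1: no sample columns found")
    return df


def _read_matrix_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ParseError(f"{path}: line 1: expected GCT version '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ParseError(f"{path}: line 2: expected '<rows>\\t<columns>'")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError:
            raise ParseError(f"{path}: line 2: non-integer dimensions {dims!r}") from None
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise ParseError(
            f"{path}: declared {n_rows} rows x {n_cols} columns but parsed "
            f"{df.shape[0]} x {df.shape[1]}"
        )
    return df


def _looks_like_gct(path: Path) -> bool:
    if str(path).lower().endswith(".gct"):
        return True
    with open(path) as fh:
        return fh.readline().startswith("#1.2")


def _assign_case_control(class_names: list[str], case_class: str | None) -> dict[str, str]:
    """Map the two observed class names onto case/control.

    If ``case_class`` is given it wins; else recognisable names (control,
    wt, tumor, ...) are honoured; else the first-listed class is control.
    """
    if len(class_names) != 2:
        raise ValidationError(
            f"expected exactly 2 phenotype classes, got {class_names}"
        )
    a, b = class_names
    if case_class is not None:
        if case_class not in class_names:
            raise ValidationError(
                f"case class {case_class!r} not among classes {class_names}"
            )
        return {case_class: CASE, (b if case_class == a else a): CONTROL}
    la, lb = a.lower(), b.lower()
    if la in _CONTROL_SYNONYMS or lb in _CASE_SYNONYMS:
        return {a: CONTROL, b: CASE}
    if lb in _CONTROL_SYNONYMS or la in _CASE_SYNONYMS:
        return {a: CASE, b: CONTROL}
    return {a: CONTROL, b: CASE}


def read_cls(path: Path, case_class: str | None = None) -> list[str]:
    """Parse a CLS file into a positional case/control label list."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}: CLS file needs 3 non-empty lines, got {len(lines)}")
    head = lines[0].split()
    if len(head) < 2:
        raise ParseError(f"{path}: line 1: expected '<n_samples> <n_classes> 1'")
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except ValueError:
        raise ParseError(f"{path}: line 1: non-integer counts {head!r}") from None
    if n_classes != 2:
        raise ValidationError(f"{path}: need exactly 2 classes, file declares {n_classes}")
    if not lines[1].startswith("#"):
        raise ParseError(f"{path}: line 2: expected '# <name1> <name2>'")
    declared = lines[1][1:].split()
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(
            f"{path}: line 3: declared {n_samples} samples but found {len(tokens)} labels"
        )
    # tokens may be the class names themselves or 0/1 indices into line 2
    uniq = list(dict.fromkeys(tokens))
    if len(uniq) != 2:
        raise ValidationError(f"{path}: labels use {len(uniq)} distinct values, need 2")
    if set(uniq) <= {"0", "1"} and not set(declared) <= {"0", "1"}:
        names = declared if len(declared) == 2 else ["0", "1"]
        tokens = [names[int(t)] for t in tokens]
        uniq = list(dict.fromkeys(names))
    order = declared if len(declared) == 2 and set(declared) == set(uniq) else uniq
    mapping = _assign_case_control(order, case_class)
    return [mapping[t] for t in tokens]


def read_labels_tsv(path: Path, case_class: str | None = None) -> dict[str, str]:
    """Two-column sample/class TSV -> {sample_id: case|control}."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {i}: expected 2 tab-separated fields")
            rows.append((parts[0].strip(), parts[1].strip()))
    if rows and rows[0][0].lower() in {"sample", "sample_id", "id"}:
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no label rows found")
    classes = list(dict.fromkeys(cls for _, cls in rows))
    mapping = _assign_case_control(classes, case_class)
    out: dict[str, str] = {}
    for sample, cls in rows:
        if sample in out:
            raise ValidationError(f"{path}: duplicate sample {sample!r}")
        out[sample] = mapping[cls]
    return out


def read_expression(
    matrix_path,
    labels_path,
    *,
    duplicate_policy: str = "max_mean",
    missing_policy: str = "drop",
    case_class: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix (TSV or GCT 1.2) with two-class labels.

    Labels come from a CLS file (positional) or a two-column TSV
    (aligned to matrix columns by sample identifier).  Duplicate gene rows
    are collapsed per ``duplicate_policy``: ``max_mean`` (default, keep the
    row with the highest mean expression), ``mean`` (average rows) or
    ``error``.  ``missing_policy`` is ``drop`` (drop genes with any missing
    value, logged) or ``error``.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    if not matrix_path.exists():
        raise ValidationError(f"expression matrix not found: {matrix_path}")
    if not labels_path.exists():
        raise ValidationError(f"labels file not found: {labels_path}")
    df = _read_matrix_gct(matrix_path) if _looks_like_gct(matrix_path) else _read_matrix_tsv(matrix_path)
    df.index = df.index.astype(str).str.upper()
    df = df.apply(pd.to_numeric, errors="coerce")

    # missing values
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        if missing_policy == "drop":
            log.warning("dropping %d gene(s) with missing values", n_missing)
            df = df.dropna(axis=0)
        else:
            raise ValidationError(f"{n_missing} gene(s) have missing values")

    # duplicate gene rows
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        if duplicate_policy == "error":
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene rows: {dupes[:10]}")
        if duplicate_policy == "mean":
            df = df.groupby(level=0, sort=False).mean()
        elif duplicate_policy == "max_mean":
            # keep, per gene, the row with the largest mean expression;
            # stable sort keeps first-seen order among exact ties
            first_seen = {g: i for i, g in reversed(list(enumerate(df.index)))}
            order = np.argsort(-df.mean(axis=1).to_numpy(), kind="stable")
            df = df.iloc[order]
            df = df[~df.index.duplicated(keep="first")]
            df = df.iloc[np.argsort([first_seen[g] for g in df.index], kind="stable")]
        else:
            raise ValidationError(f"unknown duplicate policy {duplicate_policy!r}")
        log.info("collapsed %d duplicate gene row(s) via %s", n_dup, duplicate_policy)

    samples = [str(c) for c in df.columns]

    if str(labels_path).lower().endswith(".cls"):
        labels = read_cls(labels_path, case_class=case_class)
        if len(labels) != len(samples):
            raise ValidationError(
                f"CLS file has {len(labels)} labels but matrix has {len(samples)} samples"
            )
        label_arr = np.array(labels, dtype=object)
    else:
        by_id = read_labels_tsv(labels_path, case_class=case_class)
        missing = [s for s in by_id if s not in samples]
        if missing:
            raise ValidationError(
                f"samples in labels absent from matrix: {missing[:10]}"
            )
        unlabelled = [s for s in samples if s not in by_id]
        if unlabelled:
            raise ValidationError(
                f"matrix samples without labels: {unlabelled[:10]}"
            )
        label_arr = np.array([by_id[s] for s in samples], dtype=object)

    return ExpressionDataset(
        genes=list(df.index),
        samples=samples,
        values=df.to_numpy(dtype=float),
        labels=label_arr,
    )


def write_expression(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write a dataset back out as TSV matrix + CLS labels."""
    df = pd.DataFrame(ds.values, index=pd.Index(ds.genes, name="gene"), columns=ds.samples)
    df.to_csv(matrix_path, sep="\t", float_format="%.10g")
    with open(labels_path, "w") as fh:
        fh.write(f"{len(ds.samples)} 2 1\n# control case\n")
        fh.write(" ".join(ds.labels) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """MSigDB GMT dialect: one set per line -- name, description, symbols."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene-set file not found: {path}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {i}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}: line {i}: gene set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}: line {i}: duplicate gene-set name {name!r}")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in gsc.names():
            genes = "\t".join(sorted(gsc.genes(name)))
            fh.write(f"{name}\t{gsc.description(name)}\t{genes}\n")


# ---------------------------------------------------------------------------
# physical interactions (two-column TSV)
# ---------------------------------------------------------------------------

def read_ppi(path) -> PhysicalInteractionNetwork:
    """Two-column TSV of interacting symbols; dedup + self-loops dropped."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"interaction file not found: {path}")
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {i}: expected 2 symbols")
            a, b = parts[0].upper(), parts[1].upper()
            if a == b:
                n_self += 1
                continue
            edges.add((a, b) if a < b else (b, a))
    if n_self:
        log.info("dropped %d self-loop(s) from %s", n_self, path)
    if not edges:
        log.warning("interaction network %s is empty", path)
    return PhysicalInteractionNetwork(edges)


def write_ppi(ppi: PhysicalInteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# dysregulation networks (SIF / GraphML / TSV)
# ---------------------------------------------------------------------------

_FORMATS = ("sif", "graphml", "tsv")


def _net_to_nx(net) -> nx.Graph:
    G = nx.Graph()
    for node, info in sorted(net.nodes.items()):
        G.add_node(
            node,
            pathways=",".join(sorted(info.pathways)),
            degree=int(info.degree),
            cross_pathway=bool(info.cross_pathway),
            de_q=float(info.de_q) if info.de_q is not None else -1.0,
        )
    for e in sorted(net.edges, key=lambda e: (e.gene_i, e.gene_j)):
        attrs = {
            "kinds": ",".join(sorted(k.value for k in e.kinds)),
            "pathways": ",".join(sorted(e.pathways)),
            "physical": bool(e.physical),
        }
        for k in sorted(e.p_by_kind, key=lambda k: k.value):
            attrs[f"p_{k.value}"] = float(e.p_by_kind[k])
        G.add_edge(e.gene_i, e.gene_j, **attrs)
    return G


def write_network(net, path, format: str = "graphml") -> None:
    """Export a dysregulation network as SIF, GraphML or TSV tables.

    SIF uses the profile name as the relation token (one line per pair and
    profile).  GraphML carries all edge/node attributes.  TSV writes an
    edge table to ``path`` and a node table next to it (suffix
    ``.nodes.tsv``).
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValidationError(f"unknown network format {format!r}; use one of {_FORMATS}")
    if format == "sif":
        with open(path, "w") as fh:
            for e in sorted(net.edges, key=lambda e: (e.gene_i, e.gene_j)):
                for kind in sorted(k.value for k in e.kinds):
                    fh.write(f"{e.gene_i}\t{kind}\t{e.gene_j}\n")
        return
    if format == "graphml":
        nx.write_graphml(_net_to_nx(net), path)
        return
    # tsv
    edge_cols = ["gene_i", "gene_j", "kinds", "pathways", "physical"] + [
        f"p_{k.value}" for k in _kind_order()
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(edge_cols)
        for e in sorted(net.edges, key=lambda e: (e.gene_i, e.gene_j)):
            row = [
                e.gene_i,
                e.gene_j,
                ",".join(sorted(k.value for k in e.kinds)),
                ",".join(sorted(e.pathways)),
                int(e.physical),
            ]
            for k in _kind_order():
                row.append(f"{e.p_by_kind[k]:.10g}" if k in e.p_by_kind else "")
            w.writerow(row)
    node_path = path.with_suffix(path.suffix + ".nodes.tsv") if path.suffix != ".tsv" \
        else path.with_name(path.name[: -len(".tsv")] + ".nodes.tsv")
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "degree", "pathways", "cross_pathway", "de_q"])
        for node, info in sorted(net.nodes.items()):
            w.writerow(
                [
                    node,
                    int(info.degree),
                    ",".join(sorted(info.pathways)),
                    int(info.cross_pathway),
                    f"{info.de_q:.10g}" if info.de_q is not None else "",
                ]
            )


def _kind_order():
    from .profiles import ProfileKind

    return list(ProfileKind)


def read_network(path, format: str = "graphml"):
    """Read back a network written by :func:`write_network`.

    SIF recovers pairs and profile kinds only; GraphML and TSV recover all
    attributes.  Returns a :class:`giena.network.DysregulationNetwork`.
    """
    from .network import DysregulationNetwork, InteractionEdge, NodeInfo
    from .profiles import ProfileKind

    path = Path(path)
    if format not in _FORMATS:
        raise ValidationError(f"unknown network format {format!r}; use one of {_FORMATS}")
    edges: dict[tuple[str, str], InteractionEdge] = {}
    nodes: dict[str, NodeInfo] = {}
    if format == "sif":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise ParseError(f"{path}: line {i}: expected 'a<TAB>relation<TAB>b'")
                a, kind, b = parts
                a, b = min(a, b), max(a, b)
                e = edges.setdefault(
                    (a, b),
                    InteractionEdge(gene_i=a, gene_j=b, kinds=set(), p_by_kind={}, pathways=set()),
                )
                e.kinds.add(ProfileKind.coerce(kind))
        net = DysregulationNetwork.from_edges(list(edges.values()))
        return net
    if format == "graphml":
        G = nx.read_graphml(path)
        for a, b, d in G.edges(data=True):
            a, b = min(a, b), max(a, b)
            kinds = {ProfileKind.coerce(k) for k in d.get("kinds", "").split(",") if k}
            p_by_kind = {
                k: float(d[f"p_{k.value}"]) for k in kinds if f"p_{k.value}" in d
            }
            pathways = {p for p in d.get("pathways", "").split(",") if p}
            edges[(a, b)] = InteractionEdge(
                gene_i=a, gene_j=b, kinds=kinds, p_by_kind=p_by_kind,
                pathways=pathways, physical=bool(d.get("physical", False)),
            )
        net = DysregulationNetwork.from_edges(list(edges.values()))
        for n, d in G.nodes(data=True):
            if n in net.nodes and "de_q" in d:
                q = float(d["de_q"])
                net.nodes[n].de_q = None if q < 0 else q
        return net
    # tsv
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            a, b = row["gene_i"], row["gene_j"]
            kinds = {ProfileKind.coerce(k) for k in row["kinds"].split(",") if k}
            p_by_kind = {}
            for k in kinds:
                v = row.get(f"p_{k.value}", "")
                if v:
                    p_by_kind[k] = float(v)
            edges[(a, b)] = InteractionEdge(
                gene_i=a, gene_j=b, kinds=kinds, p_by_kind=p_by_kind,
                pathways={p for p in row["pathways"].split(",") if p},
                physical=bool(int(row["physical"])),
            )
    return DysregulationNetwork.from_edges(list(edges.values()))
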