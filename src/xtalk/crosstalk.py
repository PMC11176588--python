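"""Pathway cross-talk detection from a consensus co-expression network.

Two pathways A and B are in cross-talk when the co-expression network bridges
their gene sets in a way that cannot be explained by a single chance pair:

* **bridge_pair** (criterion i): at least two distinct co-expressed gene
  pairs, each joining an A-exclusive gene to a B-exclusive gene.  The two
  pairs may share a gene; requiring two pairs is what guards against a
  single spurious pair creating a false cross-talk.
* **shared_gene** (criterion ii): a gene shared by A and B that is
  co-expressed with at least one A-exclusive gene and at least one
  B-exclusive gene, i.e. a path a - s - b through the overlap.

The union of all supporting gene pairs over all cross-talk edges is the
pathway cross-talk interface gene network (PathGeNet).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .coexpression import CoexpressionNetwork, canonical_pair

logger = logging.getLogger(__name__)

EXCLUSIVE_A = "exclusive_A"
EXCLUSIVE_B = "exclusive_B"
SHARED = "shared"
NEITHER = "neither"

BRIDGE_PAIR = "bridge_pair"
SHARED_GENE = "shared_gene"


class GMTError(ValueError):
    """Raised for malformed gene-set (GMT) input."""


@dataclass
class PathwayCollection:
    """Named gene sets with an optional pathway -> category mapping."""

    pathways: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, g in self.pathways.items() if not g]
        if empty:
            raise GMTError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.pathways)

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    def genes(self) -> set[str]:
        out: set[str] = set()
        for g in self.pathways.values():
            out |= g
        return out


@dataclass(frozen=True)
class CrosstalkEvidence:
    """Why one pathway pair is called a cross-talk.

    ``criterion`` is ``bridge_pair`` when criterion (i) holds (preferred when
    both do), else ``shared_gene``.  ``gene_pairs`` is the union of all
    supporting co-expressed pairs from every satisfied criterion, and
    ``roles`` tags each participating gene relative to (A, B).
    """

    criterion: str
    gene_pairs: frozenset[tuple[str, str]]
    roles: Mapping[str, str]


@dataclass
class CrosstalkNetwork:
    """Pathway-pair edges, each justified by CrosstalkEvidence."""

    state: str
    edges: dict[tuple[str, str], CrosstalkEvidence]

    @property
    def nodes(self) -> set[str]:
        """Pathways participating in at least one cross-talk (non-isolated)."""
        return {p for pair in self.edges for p in pair}

    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pathway_a": a,
                "pathway_b": b,
                "criterion": ev.criterion,
                "n_support_pairs": len(ev.gene_pairs),
            }
            for (a, b), ev in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["pathway_a", "pathway_b", "criterion", "n_support_pairs"]
        )


@dataclass
class PathGeNet:
    """Gene-level interface network: co-expressed pairs backing cross-talk."""

    state: str
    edges: frozenset[tuple[str, str]]

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["gene_a", "gene_b"])


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read gene sets in GMT format: id, description, then member genes.

    Gene symbols are upper-cased; duplicates within a set collapse.
    """
    pathways: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            pid, desc, *genes = fields
            pathways[pid] = frozenset(g.strip().upper() for g in genes if g.strip())
            names[pid] = desc
    if not pathways:
        logger.warning("%s: empty GMT file", path)
    return PathwayCollection(pathways, names)


def read_categories(path: str | Path) -> dict[str, str]:
    """Two-column TSV: pathway id, category label."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def filter_pathways(
    pc: PathwayCollection,
    universe: Iterable[str],
    min_genes: int = 5,
    excluded_categories: Iterable[str] = (),
) -> PathwayCollection:
    """Apply the pathway selection rules before cross-talk construction.

    (i) intersect each gene set with the measured gene universe and require
    at least ``min_genes`` genes remaining; (ii) drop excluded categories
    (e.g. human-disease and drug-development pathway classes); (iii) keep
    only pathways that share at least two genes with some other retained
    pathway.  Rule (iii) is applied once over the survivors of (i)-(ii),
    not iterated to a fixpoint.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise GMTError("empty gene universe")
    excluded = set(excluded_categories)
    trimmed: dict[str, frozenset[str]] = {}
    for pid, genes in pc.pathways.items():
        if pc.categories.get(pid) in excluded:
            continue
        inter = genes & universe
        if len(inter) >= min_genes:
            trimmed[pid] = frozenset(inter)
    pids = sorted(trimmed)
    keep: set[str] = set()
    for i, a in enumerate(pids):
        for b in pids[i + 1 :]:
            if len(trimmed[a] & trimmed[b]) >= 2:
                keep.add(a)
                keep.add(b)
    result = {p: trimmed[p] for p in pids if p in keep}
    if not result:
        logger.warning("pathway filter removed every pathway")
    return PathwayCollection(
        result,
        {p: pc.names.get(p, p) for p in result},
        {p: pc.categories[p] for p in result if p in pc.categories},
    )


def classify_gene(gene: str, a_genes: frozenset[str], b_genes: frozenset[str]) -> str:
    """Role of a gene relative to a pathway pair (A, B)."""
    in_a = gene in a_genes
    in_b = gene in b_genes
    if in_a and in_b:
        return SHARED
    if in_a:
        return EXCLUSIVE_A
    if in_b:
        return EXCLUSIVE_B
    return NEITHER


def detect_crosstalk(
    a_genes: frozenset[str],
    b_genes: frozenset[str],
    net: CoexpressionNetwork | Iterable[tuple[str, str]],
    _adjacency: dict[str, set[str]] | None = None,
) -> CrosstalkEvidence | None:
    """Evaluate the two bridging criteria for one pathway pair.

    ``net`` may be a CoexpressionNetwork or a bare iterable of gene pairs.
    Returns None when neither criterion holds.  Symmetric in (A, B) up to
    the exclusive_A/exclusive_B role labels.
    """
    if _adjacency is not None:
        adj = _adjacency
    elif isinstance(net, CoexpressionNetwork):
        adj = net.adjacency()
    else:
        adj = {}
        for u, v in net:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)

    excl_a = a_genes - b_genes
    excl_b = b_genes - a_genes
    shared = a_genes & b_genes

    bridge_pairs: set[tuple[str, str]] = set()
    for g in excl_a:
        for h in adj.get(g, ()):
            if h in excl_b:
                bridge_pairs.add(canonical_pair(g, h))

    shared_pairs: set[tuple[str, str]] = set()
    roles: dict[str, str] = {}
    for s in shared:
        nbrs = adj.get(s, set())
        ka = nbrs & excl_a
        kb = nbrs & excl_b
        if ka and kb:
            roles[s] = SHARED
            for g in ka:
                shared_pairs.add(canonical_pair(g, s))
                roles[g] = EXCLUSIVE_A
            for g in kb:
                shared_pairs.add(canonical_pair(s, g))
                roles[g] = EXCLUSIVE_B

    crit_i = len(bridge_pairs) >= 2
    crit_ii = bool(shared_pairs)
    if not crit_i and not crit_ii:
        return None
    pairs: set[tuple[str, str]] = set()
    if crit_i:
        pairs |= bridge_pairs
        for u, v in bridge_pairs:
            roles[u] = EXCLUSIVE_A if u in excl_a else EXCLUSIVE_B
            roles[v] = EXCLUSIVE_A if v in excl_a else EXCLUSIVE_B
    if crit_ii:
        pairs |= shared_pairs
    return CrosstalkEvidence(
        BRIDGE_PAIR if crit_i else SHARED_GENE, frozenset(pairs), roles
    )


def build_crosstalk_network(
    pc: PathwayCollection,
    net: CoexpressionNetwork,
) -> tuple[CrosstalkNetwork, PathGeNet]:
    """Evaluate every pathway pair against the consensus network.

    Returns the pathway-level cross-talk network and the PathGeNet, the
    union of all evidence gene pairs.
    """
    adj = net.adjacency()
    edges: dict[tuple[str, str], CrosstalkEvidence] = {}
    support: set[tuple[str, str]] = set()
    pids = sorted(pc.pathways)
    for i, a in enumerate(pids):
        for b in pids[i + 1 :]:
            ev = detect_crosstalk(pc.pathways[a], pc.pathways[b], net, _adjacency=adj)
            if ev is not None:
                edges[(a, b)] = ev
                support |= ev.gene_pairs
    logger.info(
        "%s state: %d cross-talks among %d pathways; PathGeNet %d genes / %d edges",
        net.state,
        len(edges),
        len({p for pair in edges for p in pair}),
        len({g for pr in support for g in pr}),
        len(support),
    )
    return (
        CrosstalkNetwork(net.state, edges),
        PathGeNet(net.state, frozenset(support)),
    )


def write_sif(pairs: Iterable[tuple[str, str]], path: str | Path, relation: str = "coexp") -> None:
    """Simple interaction format export (for Cytoscape-style tools)."""
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{relation}\t{b}\n")
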