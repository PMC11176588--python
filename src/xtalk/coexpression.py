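"""State-dependent gene co-expression networks and their cross-dataset consensus.

An edge joins two genes whose expression profiles, within the samples of one
state, have an absolute Pearson correlation of at least ``r_min`` (default
0.7) at a two-sided p-value below ``p_max`` (default 0.05).  The consensus
network across datasets keeps the pairs that pass those thresholds in every
dataset with the same correlation sign ("similar correlation pattern,
positive or negative"), which is what makes the per-state networks comparable
between normal and tumor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionDataset, ExpressionError

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["gene_a", "gene_b", "r", "p"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in canonical (lexicographic) order."""
    return (a, b) if a < b else (b, a)


@dataclass
class CoexpressionNetwork:
    """Undirected, sign-annotated co-expression edges for one state.

    ``edges`` has columns ``gene_a``, ``gene_b`` (canonically ordered),
    ``r`` and ``p``.  ``provenance`` records the dataset ids and thresholds
    that produced the network.
    """

    state: str
    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.edges.empty and list(self.edges.columns) != EDGE_COLUMNS:
            self.edges = pd.DataFrame(columns=EDGE_COLUMNS)
        bad = self.edges[self.edges.gene_a >= self.edges.gene_b]
        if len(bad):
            raise ValueError(f"non-canonical or self edges: {bad.head(3)}")
        pairs = list(zip(self.edges.gene_a, self.edges.gene_b))
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate unordered gene pairs in edge table")

    def __len__(self) -> int:
        return len(self.edges)

    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(zip(self.edges.gene_a, self.edges.gene_b))

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {}
        for a, b in zip(self.edges.gene_a, self.edges.gene_b):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def to_tsv(self, path) -> None:
        out = self.edges.copy()
        out["state"] = self.state
        out["dataset"] = ",".join(map(str, self.provenance.get("datasets", [])))
        out.to_csv(path, sep="\t", index=False)


def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with the classical two-sided t-test p-value.

    p is from ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom;
    a perfect correlation (|r| = 1) returns p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ExpressionError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ExpressionError("zero-variance vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for a matrix of sample correlations at size n."""
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr * rr))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(rr) >= 1.0, 0.0, p)


def state_network(
    ds: ExpressionDataset,
    state: str,
    r_min: float = 0.7,
    p_max: float = 0.05,
) -> CoexpressionNetwork:
    """All gene pairs co-expressed within one state of one dataset.

    Zero-variance genes cannot be correlated and are dropped with a log
    warning rather than failing the run.
    """
    X = ds.state_values(state)
    n = X.shape[1]
    if n < 3:
        raise ExpressionError(
            f"{ds.dataset_id}: state {state!r} has {n} samples; need >=3"
        )
    arr = X.to_numpy()
    keep = arr.std(axis=1) > 0
    if not keep.all():
        dropped = list(X.index[~keep])
        logger.warning(
            "%s/%s: dropping %d zero-variance genes from co-expression: %s",
            ds.dataset_id, state, len(dropped), dropped[:5],
        )
    genes = X.index[keep]
    arr = arr[keep]
    if len(genes) < 2:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    else:
        r = np.corrcoef(arr)
        p = _corr_pvalues(r, n)
        iu, ju = np.triu_indices(len(genes), k=1)
        mask = (np.abs(r[iu, ju]) >= r_min) & (p[iu, ju] < p_max)
        ga = genes.to_numpy()[iu[mask]]
        gb = genes.to_numpy()[ju[mask]]
        swap = ga > gb
        ga[swap], gb[swap] = gb[swap].copy(), ga[swap].copy()
        edges = pd.DataFrame(
            {"gene_a": ga, "gene_b": gb, "r": r[iu, ju][mask], "p": p[iu, ju][mask]}
        ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    prov = {"datasets": [ds.dataset_id], "r_min": r_min, "p_max": p_max, "n_samples": n}
    return CoexpressionNetwork(state, edges, prov)


def consensus_network(nets: Sequence[CoexpressionNetwork]) -> CoexpressionNetwork:
    """Sign-consistent intersection of per-dataset networks for one state.

    An edge survives when present in every input network with the same sign
    of r; the stored r is the arithmetic mean across datasets and the stored
    p is the worst (largest) per-dataset p.
    """
    if not nets:
        raise ExpressionError("need at least one network")
    states = {net.state for net in nets}
    if len(states) != 1:
        raise ExpressionError(f"cannot build a consensus across states {sorted(states)}")
    merged = nets[0].edges[EDGE_COLUMNS].rename(columns={"r": "r_0", "p": "p_0"})
    for k, net in enumerate(nets[1:], start=1):
        merged = merged.merge(
            net.edges[EDGE_COLUMNS].rename(columns={"r": f"r_{k}", "p": f"p_{k}"}),
            on=["gene_a", "gene_b"],
            how="inner",
        )
    r_cols = [f"r_{k}" for k in range(len(nets))]
    p_cols = [f"p_{k}" for k in range(len(nets))]
    if merged.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    else:
        signs = np.sign(merged[r_cols].to_numpy())
        consistent = np.all(signs == signs[:, [0]], axis=1)
        merged = merged[consistent]
        edges = pd.DataFrame(
            {
                "gene_a": merged.gene_a,
                "gene_b": merged.gene_b,
                "r": merged[r_cols].mean(axis=1),
                "p": merged[p_cols].max(axis=1),
            }
        ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    datasets = [d for net in nets for d in net.provenance.get("datasets", [])]
    prov = dict(nets[0].provenance)
    prov["datasets"] = datasets
    return CoexpressionNetwork(nets[0].state, edges, prov)


def read_network_tsv(path, state: str | None = None) -> CoexpressionNetwork:
    df = pd.read_csv(path, sep="\t")
    if state is None:
        state = str(df["state"].iloc[0]) if "state" in df and len(df) else "tumor"
    edges = df[EDGE_COLUMNS] if len(df) else pd.DataFrame(columns=EDGE_COLUMNS)
    return CoexpressionNetwork(state, edges.reset_index(drop=True))
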