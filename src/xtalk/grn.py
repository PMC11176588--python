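"""Gene dysregulation scoring over a directed gene regulatory network.

For a directed edge i -> j the per-sample regulation strength is the log
expression ratio r_ij = log(E_i / E_j) on linear-scale abundances (log2
matrices are exponentiated first, so for base 2 this is just the difference
of the stored log2 values).  The dysregulation strength of the edge is the
difference of state-averaged regulation strengths,

    ds_ij = mean_tumor(r_ij) - mean_normal(r_ij),

and its significance is assessed with a two-sided Welch t-test on the
per-sample r_ij between states.  A gene's dysregulation score d_i sums the
absolute ds over all its significant incident edges (upstream and
downstream); scores are standardised to Z across all scored genes within a
dataset.  Z is invariant to the log base, which only rescales every ds by
one constant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import NORMAL, TUMOR, ExpressionDataset, ExpressionError

logger = logging.getLogger(__name__)

PREDICTED_LABEL = "predicted"


class GRNError(ValueError):
    """Raised for malformed GRN input or unusable score requests."""


@dataclass
class DirectedGRN:
    """Directed regulator -> target interactions with optional labels."""

    edges: list[tuple[str, str]]
    labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dedup: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for i, j in self.edges:
            if i == j:
                raise GRNError(f"self-loop {i} -> {j}")
            if (i, j) not in seen:
                seen.add((i, j))
                dedup.append((i, j))
        self.edges = dedup

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)

    def exclude_label(self, label: str = PREDICTED_LABEL) -> "DirectedGRN":
        """Drop edges carrying a given interaction label (e.g. predicted)."""
        kept = [e for e in self.edges if self.labels.get(e) != label]
        return DirectedGRN(kept, {e: l for e, l in self.labels.items() if l != label})

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for i, j in self.edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        return deg


def read_grn(path: str | Path, exclude_predicted: bool = True) -> DirectedGRN:
    """Read a TSV of (regulator, target[, interaction_type]) directed edges."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GRNError(f"{path}: need at least two columns (regulator, target)")
    reg = df.iloc[:, 0].str.upper()
    tgt = df.iloc[:, 1].str.upper()
    labels: dict[tuple[str, str], str] = {}
    if df.shape[1] >= 3:
        for i, j, lab in zip(reg, tgt, df.iloc[:, 2]):
            if isinstance(lab, str) and lab:
                labels[(i, j)] = lab
    grn = DirectedGRN(list(zip(reg, tgt)), labels)
    if exclude_predicted:
        n0 = len(grn)
        grn = grn.exclude_label(PREDICTED_LABEL)
        if len(grn) < n0:
            logger.info("%s: excluded %d predicted interactions", path, n0 - len(grn))
    return grn


def regulation_strength(e_i: float, e_j: float, base: float = 2) -> float:
    """log_base(E_i / E_j) for linear-scale expression values."""
    if e_i <= 0 or e_j <= 0:
        raise GRNError("regulation strength needs positive linear-scale expression")
    return math.log(e_i / e_j, base)


def edge_dysregulation(
    x_i: np.ndarray,
    x_j: np.ndarray,
    y_i: np.ndarray,
    y_j: np.ndarray,
    base: float = 2,
) -> tuple[float, float, float, float]:
    """(r_bar_normal, r_bar_tumor, ds, p) for one edge.

    ``x_*`` are linear-scale per-sample values in the normal state, ``y_*``
    in the tumor state.  The p-value is a two-sided Welch t-test comparing
    per-sample regulation strengths between states.
    """
    arrs = [np.asarray(a, dtype=float) for a in (x_i, x_j, y_i, y_j)]
    if any((a <= 0).any() for a in arrs):
        raise GRNError("regulation strength needs positive linear-scale expression")
    x_i, x_j, y_i, y_j = arrs
    if len(x_i) < 2 or len(y_i) < 2:
        raise GRNError("need >=2 samples per state")
    ln_b = math.log(base)
    r_n = (np.log(x_i) - np.log(x_j)) / ln_b
    r_t = (np.log(y_i) - np.log(y_j)) / ln_b
    r_bar_n = float(r_n.mean())
    r_bar_t = float(r_t.mean())
    ds = r_bar_t - r_bar_n
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(r_t, r_n, equal_var=False)
    if not np.isfinite(p):
        p = 1.0 if np.isclose(ds, 0.0) else 0.0
    return r_bar_n, r_bar_t, ds, float(p)


def edge_dysregulation_table(
    grn: DirectedGRN,
    ds_set: ExpressionDataset,
    base: float = 2,
) -> pd.DataFrame:
    """Per-edge regulation/dysregulation strengths for one dataset.

    GRN edges whose genes are not measured in the dataset are skipped with
    a log entry.  The dataset's log2 matrix is exponentiated to linear scale
    before forming the ratios.

    Returns columns ``gene_i``, ``gene_j``, ``r_bar_normal``,
    ``r_bar_tumor``, ``ds``, ``ds_p_value``.
    """
    present = set(ds_set.genes)
    usable = [(i, j) for i, j in grn.edges if i in present and j in present]
    skipped = len(grn.edges) - len(usable)
    if skipped:
        logger.info(
            "%s: skipped %d GRN edges with unmeasured genes", ds_set.dataset_id, skipped
        )
    if not usable:
        return pd.DataFrame(
            columns=["gene_i", "gene_j", "r_bar_normal", "r_bar_tumor", "ds", "ds_p_value"]
        )
    for state in (NORMAL, TUMOR):
        if len(ds_set.state_samples(state)) < 2:
            raise ExpressionError(
                f"{ds_set.dataset_id}: state {state!r} needs >=2 samples"
            )
    log2 = ds_set.values
    idx = {g: k for k, g in enumerate(log2.index)}
    arr_n = log2.loc[:, ds_set.state_samples(NORMAL)].to_numpy()
    arr_t = log2.loc[:, ds_set.state_samples(TUMOR)].to_numpy()
    ii = np.array([idx[i] for i, _ in usable])
    jj = np.array([idx[j] for _, j in usable])
    scale = 1.0 / math.log2(base)
    r_n = (arr_n[ii] - arr_n[jj]) * scale
    r_t = (arr_t[ii] - arr_t[jj]) * scale
    r_bar_n = r_n.mean(axis=1)
    r_bar_t = r_t.mean(axis=1)
    ds = r_bar_t - r_bar_n
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(r_t, r_n, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, np.where(np.isclose(ds, 0.0), 1.0, 0.0))
    return pd.DataFrame(
        {
            "gene_i": [i for i, _ in usable],
            "gene_j": [j for _, j in usable],
            "r_bar_normal": r_bar_n,
            "r_bar_tumor": r_bar_t,
            "ds": ds,
            "ds_p_value": p,
        }
    )


def gene_dysregulation_scores(
    edge_table: pd.DataFrame,
    sig_p: float = 0.05,
    signed: bool = False,
) -> pd.DataFrame:
    """Per-gene dysregulation scores and Z over one dataset's edge table.

    ``d`` sums |ds| (or signed ds when ``signed``) over a gene's incident
    edges with ``ds_p_value < sig_p``; genes with measurable incident edges
    but none significant score 0.  ``z`` standardises d over all scored
    genes (sample standard deviation).  When every d is identical the Z
    signal is absent and z is set to 0 for all genes.

    Returns a DataFrame indexed by gene with columns ``d``, ``z``, ``n_i``.
    """
    genes = sorted(set(edge_table.gene_i) | set(edge_table.gene_j))
    if len(genes) < 3:
        raise GRNError(f"only {len(genes)} scored genes; need >=3 for Z-scores")
    d = dict.fromkeys(genes, 0.0)
    n_i: dict[str, int] = dict.fromkeys(genes, 0)
    sig = edge_table.ds_p_value.to_numpy() < sig_p
    ds_vals = edge_table.ds.to_numpy()
    contrib = ds_vals if signed else np.abs(ds_vals)
    for gi, gj, s, c in zip(edge_table.gene_i, edge_table.gene_j, sig, contrib):
        n_i[gi] += 1
        n_i[gj] += 1
        if s:
            d[gi] += c
            d[gj] += c
    dv = np.array([d[g] for g in genes])
    sd = dv.std(ddof=1)
    if sd == 0:
        logger.warning("all dysregulation scores identical; Z set to 0")
        z = np.zeros_like(dv)
    else:
        z = (dv - dv.mean()) / sd
    return pd.DataFrame({"d": dv, "z": z, "n_i": [n_i[g] for g in genes]}, index=pd.Index(genes, name="gene"))


def intersect_high_z(
    results: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    z_min: float = 5.0,
) -> set[str]:
    """Genes reaching ``z >= z_min`` in every dataset's score table."""
    tables = list(results.values()) if isinstance(results, Mapping) else list(results)
    if not tables:
        raise GRNError("need at least one dysregulation result")
    common: set[str] | None = None
    for t in tables:
        high = set(t.index[t.z >= z_min])
        common = high if common is None else common & high
    return common or set()
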