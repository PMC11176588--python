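"""State-labelled expression matrices and differential expression.

Expression values are assumed to be on a log2 scale (normalised microarray
intensities or log-transformed RNA-seq abundances).  Each dataset carries a
per-sample state label, ``"normal"`` or ``"tumor"``, and all state-dependent
operations (differential expression, state co-expression networks, GRN
dysregulation) split the sample columns on that label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOR = "tumor"
STATES = (NORMAL, TUMOR)


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression inputs."""


@dataclass
class ExpressionDataset:
    """A genes x samples log2 expression matrix with per-sample state labels.

    Parameters
    ----------
    dataset_id
        Free-text identifier (e.g. a GEO accession).
    values
        DataFrame indexed by unique gene symbols, columns are sample ids.
    states
        Series mapping each sample id to ``"normal"`` or ``"tumor"``, indexed
        identically to ``values.columns``.
    """

    dataset_id: str
    values: pd.DataFrame
    states: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionError(
                f"{self.dataset_id}: duplicate gene symbols {list(dupes)[:5]}"
            )
        missing = [s for s in self.values.columns if s not in self.states.index]
        if missing:
            raise ExpressionError(
                f"{self.dataset_id}: samples without a state label: {missing[:5]}"
            )
        self.states = self.states.reindex(self.values.columns)
        bad = set(self.states.unique()) - set(STATES)
        if bad:
            raise ExpressionError(
                f"{self.dataset_id}: unknown state labels {sorted(bad)}; "
                f"expected one of {STATES}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError(f"{self.dataset_id}: non-numeric expression values")
        if not np.isfinite(arr).all():
            raise ExpressionError(f"{self.dataset_id}: non-finite expression values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def state_samples(self, state: str) -> pd.Index:
        if state not in STATES:
            raise ExpressionError(f"unknown state {state!r}")
        return self.states.index[self.states == state]

    def state_values(self, state: str) -> pd.DataFrame:
        """Sub-matrix restricted to samples in one state."""
        return self.values.loc[:, self.state_samples(state)]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        missing = set(genes) - set(self.genes)
        if missing:
            raise ExpressionError(
                f"{self.dataset_id}: genes absent from dataset: {sorted(missing)[:5]}"
            )
        return ExpressionDataset(self.dataset_id, self.values.loc[list(genes)], self.states)


def read_state_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample id, state label) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ExpressionError(f"{path}: state map needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression(
    path: str | Path,
    state_map: Mapping[str, str],
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a tab-separated genes x samples matrix.

    The first column holds gene symbols, the header row holds sample ids.
    Duplicate gene rows (e.g. multiple probes per symbol) are collapsed by
    their mean, with a log record.  Every sample must appear in ``state_map``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ExpressionError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("%s: collapsed %d duplicate gene rows by mean", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    missing = [s for s in df.columns if s not in state_map]
    if missing:
        raise ExpressionError(f"{path}: samples missing from state map: {missing}")
    states = pd.Series({s: state_map[s] for s in df.columns}, name="state")
    return ExpressionDataset(dataset_id or path.stem, df, states)


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene")


def intersect_genes(datasets: Sequence[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the sorted intersection of their gene sets."""
    if not datasets:
        raise ExpressionError("need at least one dataset")
    common: set[str] = set(datasets[0].genes)
    for ds in datasets[1:]:
        common &= set(ds.genes)
    if not common:
        raise ExpressionError("gene intersection across datasets is empty")
    ordered = sorted(common)
    return [ds.subset_genes(ordered) for ds in datasets]


def differential_expression(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene log2 fold change (tumor - normal) with a Welch t-test p-value.

    Operates on the log2 matrix directly, so the difference of state means is
    the log2 fold change.  Degenerate genes (zero variance in both states) get
    p = 1 when the means agree and p = 0 otherwise.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p_value``.
    """
    normal = ds.state_values(NORMAL).to_numpy()
    tumor = ds.state_values(TUMOR).to_numpy()
    for name, arr in ((NORMAL, normal), (TUMOR, tumor)):
        if arr.shape[1] < 2:
            raise ExpressionError(
                f"{ds.dataset_id}: state {name!r} has {arr.shape[1]} samples; need >=2"
            )
    lfc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(np.isclose(lfc, 0.0), 1.0, 0.0), p)
    return pd.DataFrame({"log2fc": lfc, "p_value": p}, index=ds.genes)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read an externally computed DE table: gene, log2fc, p_value (TSV)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    needed = ["gene", "log2fc", "p_value"]
    if not all(k in cols for k in needed):
        raise ExpressionError(f"{path}: DE table needs columns {needed}")
    df = df.rename(columns={cols[k]: k for k in needed}).set_index("gene")
    df.index = df.index.astype(str).str.upper()
    return df[["log2fc", "p_value"]]


def signature_genes(
    de_tables: Mapping[str, pd.DataFrame],
    lfc_min: float = 0.5,
    p_max: float = 0.01,
    gene_pool: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Cross-dataset expression signature: (up-regulated, down-regulated).

    A gene qualifies when its DE p-value is below ``p_max`` in *every*
    dataset and the absolute mean log2FC across datasets is at least
    ``lfc_min``; the sign of the mean assigns the direction.
    """
    if not de_tables:
        raise ExpressionError("need at least one DE table")
    tables = list(de_tables.values())
    if gene_pool is None:
        pool = set(tables[0].index)
        for t in tables[1:]:
            pool &= set(t.index)
    else:
        pool = set(gene_pool)
    if not pool:
        raise ExpressionError("empty gene pool for signature extraction")
    for name, t in de_tables.items():
        missing = pool - set(t.index)
        if missing:
            raise ExpressionError(
                f"gene pool not covered by DE table {name!r}: {sorted(missing)[:5]}"
            )
    genes = sorted(pool)
    lfc = pd.DataFrame({k: t.loc[genes, "log2fc"] for k, t in de_tables.items()})
    pvals = pd.DataFrame({k: t.loc[genes, "p_value"] for k, t in de_tables.items()})
    mean_lfc = lfc.mean(axis=1)
    keep = (pvals < p_max).all(axis=1) & (mean_lfc.abs() >= lfc_min)
    up = set(mean_lfc.index[keep & (mean_lfc > 0)])
    down = set(mean_lfc.index[keep & (mean_lfc < 0)])
    return up, down
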