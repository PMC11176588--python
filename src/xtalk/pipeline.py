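"""End-to-end discovery pipeline: expression -> networks -> comparison -> scores.

Stages run in the order of the underlying workflow: read and harmonise the
datasets, differential expression, per-state/per-dataset co-expression
networks, cross-dataset consensus per state, pathway filtering, cross-talk
construction per state, normal-vs-tumor comparison, connected components and
betweenness key genes, then (when the inputs are provided) GRN dysregulation
scoring and prognostic cluster evaluation, and hypergeometric pathway
enrichment of the key genes.  Every stage logs the counts surviving its
filters and the run manifest records inputs, thresholds and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import coexpression as cx
from . import crosstalk as ck
from . import expression as xp
from . import grn as gr
from . import netcompare as nc
from . import survival as sv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a discovery run.

    Thresholds default to the workflow's standard settings: DE p < 0.01,
    |mean log2FC| >= 0.5, |PCC| >= 0.7 at p < 0.05, pathways with >= 5
    measured genes, per-edge dysregulation significance p < 0.05, Z >= 5,
    top k = 10 key genes.
    """

    expression: list[str] = field(default_factory=list)
    states: list[str] = field(default_factory=list)
    gmt: str | None = None
    categories: str | None = None
    grn: str | None = None
    survival: str | None = None
    survival_expression: str | None = None
    out_dir: str = "xtalk_run"
    r_min: float = 0.7
    p_max: float = 0.05
    de_p: float = 0.01
    lfc_min: float = 0.5
    min_genes: int = 5
    excluded_categories: list[str] = field(default_factory=list)
    z_min: float = 5.0
    sig_p: float = 0.05
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= 1) or not (0 < self.p_max <= 1):
            raise ValueError("correlation thresholds out of range")
        if len(self.expression) != len(self.states):
            raise ValueError("need one state map per expression matrix")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def pathway_enrichment(
    genes: Iterable[str],
    pc: ck.PathwayCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    Gene sets are intersected with the universe; p is the upper tail of the
    hypergeometric distribution at the observed overlap, with a
    Benjamini-Hochberg adjusted column.  Sorted by p.
    """
    query = {g.upper() for g in genes}
    uni = {g.upper() for g in universe}
    if not query:
        raise ValueError("empty query gene set")
    stray = query - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    m = len(uni)
    n = len(query)
    rows = []
    for pid, pw_genes in sorted(pc.pathways.items()):
        in_uni = pw_genes & uni
        k = len(pw_genes & query)
        p = float(stats.hypergeom.sf(k - 1, m, len(in_uni), n)) if in_uni else 1.0
        rows.append(
            {"pathway": pid, "pathway_size": len(in_uni), "overlap": k, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "pathway"], ignore_index=True)
    return df


def _network_stage(
    datasets: Sequence[xp.ExpressionDataset], cfg: RunConfig
) -> dict[str, cx.CoexpressionNetwork]:
    consensus = {}
    for state in xp.STATES:
        nets = [cx.state_network(ds, state, cfg.r_min, cfg.p_max) for ds in datasets]
        consensus[state] = cx.consensus_network(nets)
        logger.info(
            "consensus %s: %d edges from %s",
            state, len(consensus[state]),
            [len(n) for n in nets],
        )
    return consensus


def run_discovery(
    cfg: RunConfig,
    study=None,
) -> dict:
    """Run every stage and return the manifest.

    ``study`` may be a pre-loaded :class:`xtalk.synthetic.SyntheticStudy`
    (used by the simulation entry points); otherwise all inputs are read
    from the paths in ``cfg``.  Artifacts are written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}}

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    # ---- load ----------------------------------------------------------
    if study is not None:
        datasets = study.datasets
        pathways = study.pathways
        grn = study.grn.exclude_label() if study.grn else None
        surv = study.survival
    else:
        datasets = [
            xp.read_expression(e, xp.read_state_map(s))
            for e, s in zip(cfg.expression, cfg.states)
        ]
        pathways = ck.read_gmt(cfg.gmt) if cfg.gmt else None
        if pathways and cfg.categories:
            pathways.categories.update(ck.read_categories(cfg.categories))
        grn = gr.read_grn(cfg.grn) if cfg.grn else None
        surv = None
        if cfg.survival and cfg.survival_expression:
            surv_expr = pd.read_csv(cfg.survival_expression, sep="\t", index_col=0)
            surv = sv.read_survival(cfg.survival, surv_expr)
    if not datasets:
        raise ValueError("no expression datasets configured")
    datasets = xp.intersect_genes(datasets)
    universe = set(datasets[0].genes)
    stage("load", n_datasets=len(datasets), n_common_genes=len(universe))

    # ---- differential expression --------------------------------------
    de_tables = {ds.dataset_id: xp.differential_expression(ds) for ds in datasets}
    for did, tab in de_tables.items():
        tab.to_csv(out / f"de_{did}.tsv", sep="\t")
    up, down = xp.signature_genes(de_tables, cfg.lfc_min, cfg.de_p, universe)
    stage("differential_expression", up=len(up), down=len(down))

    # ---- co-expression --------------------------------------------------
    consensus = _network_stage(datasets, cfg)
    for state, net in consensus.items():
        net.to_tsv(out / f"consensus_{state}.tsv")
    stage(
        "consensus",
        **{state: len(net) for state, net in consensus.items()},
    )

    # ---- cross-talk ------------------------------------------------------
    results: dict[str, tuple[ck.CrosstalkNetwork, ck.PathGeNet]] = {}
    key_rankings: dict[str, list[pd.DataFrame]] = {}
    if pathways is not None:
        filtered = ck.filter_pathways(
            pathways, universe, cfg.min_genes, cfg.excluded_categories
        )
        stage("pathway_filter", retained=len(filtered))
        for state, net in consensus.items():
            ctn, pgn = ck.build_crosstalk_network(filtered, net)
            results[state] = (ctn, pgn)
            ctn.to_frame().to_csv(out / f"crosstalk_{state}.tsv", sep="\t", index=False)
            pgn.to_frame().to_csv(out / f"pathgenet_{state}.tsv", sep="\t", index=False)
            ck.write_sif(pgn.edges, out / f"pathgenet_{state}.sif")
            stage(
                f"crosstalk_{state}",
                pathways=len(ctn.nodes),
                crosstalks=len(ctn.edges),
                pathgenet_genes=len(pgn.genes),
                pathgenet_edges=len(pgn.edges),
            )

        # ---- comparison & key genes ------------------------------------
        delta_p = nc.network_difference(
            results[xp.NORMAL][0].pair_set(), results[xp.TUMOR][0].pair_set()
        )
        delta_g = nc.network_difference(
            results[xp.NORMAL][1].edges, results[xp.TUMOR][1].edges
        )
        delta_p.to_frame().to_csv(out / "delta_pathways.tsv", sep="\t", index=False)
        delta_g.to_frame().to_csv(out / "delta_genes.tsv", sep="\t", index=False)
        stage(
            "comparison",
            pathway_only_normal=len(delta_p.only_in_a),
            pathway_only_tumor=len(delta_p.only_in_b),
            pathway_conserved=len(delta_p.conserved),
            gene_only_normal=len(delta_g.only_in_a),
            gene_only_tumor=len(delta_g.only_in_b),
            gene_conserved=len(delta_g.conserved),
        )
        for state, (_, pgn) in results.items():
            g = nc.to_graph(pgn.edges)
            comps = nc.connected_components(g)
            rankings = []
            for cid, comp in enumerate(comps[:2]):
                kr = nc.key_genes(g, comp, cfg.k, component_id=cid)
                rankings.append(kr.ranking.assign(component=cid))
            key_rankings[state] = rankings
            if rankings:
                pd.concat(rankings).to_csv(
                    out / f"key_genes_{state}.tsv", sep="\t", index=False
                )
            stage(
                f"key_genes_{state}",
                components=[len(c) for c in comps[:5]],
                top=[r.gene.tolist() for r in rankings],
            )
        # ---- enrichment of tumor key genes ------------------------------
        tumor_keys = {
            g for r in key_rankings.get(xp.TUMOR, []) for g in r.gene
        }
        if tumor_keys:
            enr = pathway_enrichment(tumor_keys, filtered, universe | tumor_keys)
            enr.to_csv(out / "key_gene_enrichment.tsv", sep="\t", index=False)
            stage("enrichment", n_query=len(tumor_keys), top=enr.pathway.head(3).tolist())
        else:
            stage("enrichment", skipped="no key genes")
    else:
        stage("crosstalk", skipped="no pathway collection")

    # ---- GRN dysregulation ----------------------------------------------
    if grn is not None and len(grn):
        z_tables = {}
        for ds in datasets:
            table = gr.edge_dysregulation_table(grn, ds)
            scores = gr.gene_dysregulation_scores(table, cfg.sig_p)
            scores.to_csv(out / f"dysregulation_{ds.dataset_id}.tsv", sep="\t")
            z_tables[ds.dataset_id] = scores
        common = gr.intersect_high_z(z_tables, cfg.z_min)
        (out / "dysregulated_genes.txt").write_text("\n".join(sorted(common)) + "\n")
        stage("dysregulation", per_dataset={k: len(v) for k, v in z_tables.items()},
              high_z_common=sorted(common))
    else:
        stage("dysregulation", skipped="no GRN provided")

    # ---- survival --------------------------------------------------------
    if surv is not None:
        cluster = sorted(
            set(surv.expression.index)
            & ({g for r in key_rankings.get(xp.TUMOR, []) for g in r.gene} or set())
        )
        if not cluster and study is not None:
            cluster = study.truth.surv_cluster
        if cluster:
            ev = sv.evaluate_cluster(cluster, surv, random_state=cfg.seed)
            pd.DataFrame(
                {"risk_score": ev.model.scores, "group": ev.model.groups}
            ).to_csv(out / "risk_scores.tsv", sep="\t", index_label="sample")
            stage(
                "survival",
                cluster=cluster,
                logrank_chi2=round(ev.logrank.chi2, 4),
                logrank_p=ev.logrank.p,
            )
        else:
            stage("survival", skipped="no cluster genes measured in cohort")
    else:
        stage("survival", skipped="no survival data provided")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
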