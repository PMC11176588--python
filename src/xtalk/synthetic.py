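"""Seed-reproducible synthetic multi-dataset studies with planted ground truth.

The generator emulates the study design the pipeline targets: several
independent paired normal/tumor expression datasets, an overlapping pathway
collection, a directed GRN, and a survival cohort.  Every planted structure
is recorded in a :class:`GroundTruth` so recovery can be measured exactly.

What is planted
---------------
* **Cross-talk blocks.**  For a pathway pair (A, B) a small gene block that
  spans the pathway boundary is drawn from a multivariate Gaussian with
  within-block correlation ``rho`` in the designated state(s) and left
  independent in the other state (rewiring).  A ``bridge_pair`` block uses
  two A-exclusive and two B-exclusive genes; a ``shared_gene`` block routes
  through one gene in the A-B overlap.  A block may be sign-flipped on one
  side to plant negative co-expression.
* **GRN shifts.**  Hub regulators keep their targets' expression shifted by
  ``grn_shift`` log2 units in tumor samples (alternating sign across
  targets), dysregulating every hub edge.
* **Survival.**  A separate cohort draws exponential proportional-hazards
  times with linear predictor ``surv_beta`` summed over a planted gene
  cluster, with independent exponential censoring.

Pathways are laid out in a chain where consecutive pathways share
``pathway_overlap`` genes, so every pathway satisfies the >=2-shared-genes
retention rule without creating unplanted cross-talk evidence (overlap genes
stay uncorrelated unless a shared_gene block recruits one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .crosstalk import BRIDGE_PAIR, SHARED_GENE, PathwayCollection
from .expression import NORMAL, TUMOR, ExpressionDataset
from .grn import DirectedGRN
from .survival import SurvivalData


@dataclass(frozen=True)
class PlantedCrosstalk:
    """One planted pathway-pair cross-talk and how it is realised."""

    pathway_a: str
    pathway_b: str
    criterion: str  # bridge_pair | shared_gene
    states: frozenset[str] = frozenset({TUMOR})
    negative: bool = False  # sign-flip one side of the block


@dataclass
class SyntheticConfig:
    """Study layout and planted effect sizes.

    Defaults describe a desk-scale study: three paired-design datasets of 20
    samples per state, eight 15-gene pathways chained with 2-gene overlaps,
    a 29-gene GRN (3 hubs x 6 targets plus an 8-gene cascade) and a
    200-patient survival cohort with a 5-gene prognostic cluster.
    """

    n_datasets: int = 3
    samples_per_state: int = 20
    n_pathways: int = 8
    pathway_size: int = 15
    pathway_overlap: int = 2
    n_background_genes: int = 40
    rho: float = 0.9
    noise_sd: float = 0.5
    module_size: int = 4  # intra-pathway rewired module planted in pathway 1
    crosstalks: tuple[PlantedCrosstalk, ...] = (
        PlantedCrosstalk("P01", "P02", BRIDGE_PAIR, frozenset({TUMOR})),
        PlantedCrosstalk("P03", "P04", SHARED_GENE, frozenset({TUMOR})),
        PlantedCrosstalk("P05", "P06", BRIDGE_PAIR, frozenset({NORMAL, TUMOR}), negative=True),
        PlantedCrosstalk("P07", "P08", BRIDGE_PAIR, frozenset({NORMAL})),
    )
    # GRN layout
    n_hubs: int = 3
    targets_per_hub: int = 6
    n_cascade_genes: int = 8
    n_predicted_edges: int = 3
    grn_shift: float = 1.0  # log2 shift of hub targets in tumor
    # survival cohort
    n_surv_samples: int = 200
    surv_cluster_size: int = 5
    surv_n_background: int = 15
    surv_beta: float = 0.5
    baseline_hazard: float = 0.1
    censor_rate: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pathway_overlap >= self.pathway_size:
            raise ValueError("pathway overlap must be smaller than pathway size")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        for ct in self.crosstalks:
            for p in (ct.pathway_a, ct.pathway_b):
                idx = int(p[1:])
                if idx > self.n_pathways:
                    raise ValueError(f"planted cross-talk names missing pathway {p}")
            if ct.criterion == SHARED_GENE:
                a, b = int(ct.pathway_a[1:]), int(ct.pathway_b[1:])
                if abs(a - b) != 1:
                    raise ValueError(
                        "shared_gene cross-talk needs adjacent (overlapping) pathways"
                    )


@dataclass
class GroundTruth:
    """Everything planted, keyed the way the pipeline reports results."""

    crosstalk_pairs: dict[str, set[tuple[str, str]]]  # state -> pathway pairs
    bridge_gene_pairs: dict[str, set[tuple[str, str]]]  # state -> gene pairs
    hub_genes: list[str]
    de_up: set[str]
    de_down: set[str]
    surv_cluster: list[str]
    surv_beta: pd.Series


@dataclass
class SyntheticStudy:
    datasets: list[ExpressionDataset]
    pathways: PathwayCollection
    grn: DirectedGRN
    survival: SurvivalData
    truth: GroundTruth
    config: SyntheticConfig


def _pathway_layout(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Chained pathway gene sets; consecutive pathways share overlap genes."""
    layout: dict[str, list[str]] = {}
    counter = 0
    prev_tail: list[str] = []
    for p in range(1, cfg.n_pathways + 1):
        n_new = cfg.pathway_size - (len(prev_tail) if p > 1 else 0)
        new = [f"PG{counter + k:04d}" for k in range(n_new)]
        counter += n_new
        genes = prev_tail + new
        layout[f"P{p:02d}"] = genes
        prev_tail = genes[-cfg.pathway_overlap :]
    return layout


def _draw_block(
    rng: np.random.Generator, n: int, size: int, rho: float, sd: float,
    flip: Iterable[int] = (),
) -> np.ndarray:
    """Equicorrelated Gaussian block via a one-factor model (size x n).

    ``flip`` lists row indices whose loading is negated, planting negative
    correlations between flipped and unflipped members.
    """
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((size, n))
    load = np.full(size, np.sqrt(rho))
    for k in flip:
        load[k] = -load[k]
    return sd * (load[:, None] * shared[None, :] + np.sqrt(1 - rho) * eps)


def generate_study(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate one full synthetic study; identical seeds give identical data."""
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    layout = _pathway_layout(cfg)
    pathway_genes = sorted({g for gs in layout.values() for g in gs})

    # --- planted cross-talk blocks -------------------------------------
    block_defs: list[tuple[list[str], frozenset[str], list[int]]] = []
    bridge_pairs: dict[str, set[tuple[str, str]]] = {NORMAL: set(), TUMOR: set()}
    ct_pairs: dict[str, set[tuple[str, str]]] = {NORMAL: set(), TUMOR: set()}
    used: set[str] = set()  # genes already recruited to a block

    def exclusive(pid: str) -> list[str]:
        others = {g for q, gs in layout.items() if q != pid for g in gs}
        return [g for g in layout[pid] if g not in others and g not in used]

    for ct in cfg.crosstalks:
        a, b = ct.pathway_a, ct.pathway_b
        if ct.criterion == BRIDGE_PAIR:
            ga = exclusive(a)[:2]
            gb = exclusive(b)[:2]
            genes = ga + gb
            flip = [2, 3] if ct.negative else []
            support = {tuple(sorted((x, y))) for x in ga for y in gb}
        else:  # shared_gene: route through one overlap gene of (a, b)
            shared = sorted(set(layout[a]) & set(layout[b]) - used)
            ga = exclusive(a)[:1]
            gb = exclusive(b)[:1]
            genes = ga + [shared[0]] + gb
            flip = []
            support = {
                tuple(sorted((ga[0], shared[0]))),
                tuple(sorted((shared[0], gb[0]))),
            }
        used.update(genes)
        block_defs.append((genes, ct.states, flip))
        for state in ct.states:
            ct_pairs[state].add(tuple(sorted((a, b))))
            bridge_pairs[state] |= support

    # intra-pathway module in P01, correlated in tumor only (rewiring)
    module = [g for g in layout["P01"] if g not in used][: cfg.module_size]
    used.update(module)
    if module:
        block_defs.append((module, frozenset({TUMOR}), []))

    # --- GRN layout ----------------------------------------------------
    hubs = [f"HUB{h:02d}" for h in range(1, cfg.n_hubs + 1)]
    grn_edges: list[tuple[str, str]] = []
    labels: dict[tuple[str, str], str] = {}
    targets: list[str] = []
    shift_sign: dict[str, float] = {}
    t_counter = 0
    for hub in hubs:
        for k in range(cfg.targets_per_hub):
            tgt = f"TGT{t_counter:03d}"
            t_counter += 1
            targets.append(tgt)
            grn_edges.append((hub, tgt))
            shift_sign[tgt] = 1.0 if k % 2 == 0 else -1.0
    cascade = [f"CAS{c:02d}" for c in range(cfg.n_cascade_genes)]
    for u, v in zip(cascade, cascade[1:]):
        grn_edges.append((u, v))
    grn_gene_list = hubs + targets + cascade
    # a few labelled predicted edges, excluded at ingestion
    for k in range(cfg.n_predicted_edges):
        e = (cascade[k % len(cascade)], hubs[k % len(hubs)])
        if e not in grn_edges:
            grn_edges.append(e)
            labels[e] = "predicted"
    grn = DirectedGRN(grn_edges, labels)

    background = [f"BG{k:03d}" for k in range(cfg.n_background_genes)]
    all_genes = pathway_genes + grn_gene_list + background
    base_mean = pd.Series(rng.uniform(6.0, 12.0, len(all_genes)), index=all_genes)

    # --- expression datasets -------------------------------------------
    datasets: list[ExpressionDataset] = []
    n = cfg.samples_per_state
    for d in range(cfg.n_datasets):
        cols: dict[str, np.ndarray] = {}
        states: dict[str, str] = {}
        mat = {}
        for state in (NORMAL, TUMOR):
            X = rng.normal(0.0, cfg.noise_sd, (len(all_genes), n))
            gi = {g: k for k, g in enumerate(all_genes)}
            for genes, active_states, flip in block_defs:
                if state in active_states:
                    X[[gi[g] for g in genes]] = _draw_block(
                        rng, n, len(genes), cfg.rho, cfg.noise_sd, flip
                    )
            if state == TUMOR and cfg.grn_shift:
                for tgt, sgn in shift_sign.items():
                    X[gi[tgt]] += sgn * cfg.grn_shift
            mat[state] = X
        sample_ids = []
        for state in (NORMAL, TUMOR):
            for s in range(n):
                sid = f"D{d + 1}_{state[0].upper()}{s:02d}"
                sample_ids.append(sid)
                states[sid] = state
        values = pd.DataFrame(
            np.hstack([mat[NORMAL], mat[TUMOR]]) + base_mean.to_numpy()[:, None],
            index=all_genes,
            columns=sample_ids,
        )
        datasets.append(
            ExpressionDataset(f"SYN{d + 1}", values, pd.Series(states, name="state"))
        )

    pc = PathwayCollection(
        {pid: frozenset(gs) for pid, gs in layout.items()},
        {pid: f"synthetic pathway {pid}" for pid in layout},
    )

    # --- survival cohort ------------------------------------------------
    cluster = [f"SURV{k:02d}" for k in range(cfg.surv_cluster_size)]
    surv_bg = [f"SBG{k:02d}" for k in range(cfg.surv_n_background)]
    surv_genes = cluster + surv_bg
    ns = cfg.n_surv_samples
    expr = rng.normal(0.0, 1.0, (len(surv_genes), ns)) + 7.0
    samples = [f"PT{k:03d}" for k in range(ns)]
    expr_df = pd.DataFrame(expr, index=surv_genes, columns=samples)
    eta = cfg.surv_beta * (expr_df.loc[cluster] - 7.0).sum(axis=0).to_numpy()
    t_event = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(eta)))
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, ns)
    else:
        t_cens = np.full(ns, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = SurvivalData(
        pd.Series(time, index=samples, name="time"),
        pd.Series(event, index=samples, name="event"),
        expr_df,
    )

    de_up = {t for t, s in shift_sign.items() if s > 0} if cfg.grn_shift else set()
    de_down = {t for t, s in shift_sign.items() if s < 0} if cfg.grn_shift else set()
    truth = GroundTruth(
        crosstalk_pairs={s: set(p) for s, p in ct_pairs.items()},
        bridge_gene_pairs={s: set(p) for s, p in bridge_pairs.items()},
        hub_genes=list(hubs) if cfg.grn_shift else [],
        de_up=de_up,
        de_down=de_down,
        surv_cluster=cluster,
        surv_beta=pd.Series(
            cfg.surv_beta if cfg.surv_beta else 0.0, index=cluster, name="beta"
        ),
    )
    return SyntheticStudy(datasets, pc, grn, survival, truth, cfg)


def generate_null_study(cfg: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Same layout with every planted effect disabled (rho=0, no shifts)."""
    cfg = cfg or SyntheticConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    null_cfg = replace(cfg, rho=0.0, grn_shift=0.0, surv_beta=0.0)
    study = generate_study(null_cfg)
    study.truth.crosstalk_pairs = {NORMAL: set(), TUMOR: set()}
    study.truth.bridge_gene_pairs = {NORMAL: set(), TUMOR: set()}
    return study


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict:
    """Write a study in the exact text formats the readers consume.

    Returns the ground-truth manifest (also written as JSON).
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in study.datasets:
        ds.values.to_csv(out / f"{ds.dataset_id}_expr.tsv", sep="\t", index_label="gene")
        ds.states.to_csv(
            out / f"{ds.dataset_id}_states.tsv", sep="\t", header=False
        )
    with open(out / "pathways.gmt", "w") as fh:
        for pid, genes in study.pathways.pathways.items():
            name = study.pathways.names.get(pid, pid)
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")
    with open(out / "grn.tsv", "w") as fh:
        fh.write("regulator\ttarget\tinteraction_type\n")
        for e in study.grn.edges:
            fh.write(f"{e[0]}\t{e[1]}\t{study.grn.labels.get(e, 'regulates')}\n")
    surv = pd.DataFrame(
        {"sample": study.survival.samples, "time": study.survival.time.values,
         "event": study.survival.event.values}
    )
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    study.survival.expression.to_csv(out / "survival_expr.tsv", sep="\t", index_label="gene")
    truth = study.truth
    manifest = {
        "seed": study.config.seed,
        "crosstalk_pairs": {s: sorted(map(list, p)) for s, p in truth.crosstalk_pairs.items()},
        "bridge_gene_pairs": {s: sorted(map(list, p)) for s, p in truth.bridge_gene_pairs.items()},
        "hub_genes": truth.hub_genes,
        "de_up": sorted(truth.de_up),
        "de_down": sorted(truth.de_down),
        "surv_cluster": truth.surv_cluster,
        "surv_beta": truth.surv_beta.to_dict(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
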