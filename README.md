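# xtalk

Pathway cross-talk — coordinated activity between biological pathways —
rewires as tissue moves from a normal to a disease state, and that rewiring
carries both mechanistic and prognostic signal. `xtalk` is a Python package
for systems biologists who have paired normal/tumor expression cohorts (e.g.
several GEO microarray series plus a TCGA cohort) and want to quantify that
rewiring end to end:

1. **State-dependent consensus co-expression.** Within each dataset and
   state, gene pairs with |PCC| ≥ 0.7 and p < 0.05 are co-expressed; the
   consensus network keeps pairs that pass in every dataset with a
   consistent correlation sign.
2. **Pathway cross-talk networks.** Two pathways A and B (gene sets from a
   GMT file, filtered for ≥5 measured genes and cross-pathway overlap) are
   in cross-talk if the consensus network contains (i) at least two
   distinct co-expressed pairs joining A-exclusive to B-exclusive genes, or
   (ii) a shared gene co-expressed with an exclusive gene on each side.
   The union of supporting gene pairs is the interface gene network
   (**PathGeNet**).
3. **Comparison and key genes.** Normal and tumor networks are partitioned
   into state-specific and conserved edges; key genes are ranked by
   betweenness centrality within PathGeNet components.
4. **GRN dysregulation.** Over a directed regulator→target network, the
   per-edge regulation strength r_ij = log₂(E_i/E_j) is averaged per state;
   ds_ij = r̄_ij^tumor − r̄_ij^normal, and each gene's dysregulation score
   d_i = Σ_j |ds_ij| over significant incident edges is standardised to a
   Z-score per dataset.
5. **Prognosis.** A gene cluster is scored per patient as the Cox linear
   predictor Σ Expᵢ·βᵢ, median-split into high/low risk and compared with
   Kaplan–Meier curves and a log-rank test (split-sample validation by
   default, so the p-value is honest).

A seeded synthetic-study generator plants every structure above
(rewired correlation blocks, bridge pairs for both criteria, shifted GRN
hubs, a prognostic cluster with known β) so the whole pipeline is testable
against ground truth.

## Worked example

```python
from xtalk import (
    generate_study, state_network, consensus_network, filter_pathways,
    build_crosstalk_network, network_difference, key_genes, to_graph,
    edge_dysregulation_table, gene_dysregulation_scores, evaluate_cluster,
)

study = generate_study(seed=1)          # 3 datasets, 20 samples/state

consensus = {
    state: consensus_network([state_network(ds, state) for ds in study.datasets])
    for state in ("normal", "tumor")
}
pathways = filter_pathways(study.pathways, set(study.datasets[0].genes))
crosstalk, pathgenet = {}, {}
for state, net in consensus.items():
    crosstalk[state], pathgenet[state] = build_crosstalk_network(pathways, net)
    print(f"{state}: {len(net)} consensus edges -> "
          f"{len(crosstalk[state].edges)} cross-talks among {len(crosstalk[state].nodes)} pathways")

delta = network_difference(crosstalk["normal"].pair_set(), crosstalk["tumor"].pair_set())
print("tumor-specific cross-talks:", sorted(delta.only_in_b))

ranking = key_genes(to_graph(pathgenet["tumor"].edges), k=3)
print("top interface genes:", ranking.ranking.gene.tolist())

grn = study.grn.exclude_label()         # drop 'predicted' interactions
scores = gene_dysregulation_scores(edge_dysregulation_table(grn, study.datasets[0]))
print("top-3 dysregulated:", scores.z.nlargest(3).round(2).to_dict())

ev = evaluate_cluster(study.truth.surv_cluster, study.survival, random_state=1)
print(f"log-rank chi2={ev.logrank.chi2:.2f} p={ev.logrank.p:.2e}")
```

prints

```
normal: 12 consensus edges -> 2 cross-talks among 4 pathways
tumor: 21 consensus edges -> 3 cross-talks among 6 pathways
tumor-specific cross-talks: [('P01', 'P02'), ('P03', 'P04')]
top interface genes: ['PG0000', 'PG0001', 'PG0015']
top-3 dysregulated: {'HUB03': 2.92, 'HUB01': 2.76, 'HUB02': 2.66}
log-rank chi2=54.47 p=1.58e-13
```

The recovered cross-talk pairs are exactly the planted ones
(`study.truth.crosstalk_pairs`): `P01–P02` (bridge pairs) and `P03–P04`
(shared-gene route) appear only in the tumor state, `P05–P06` in both, and
`P07–P08` only in normal. The three GRN hubs take the top dysregulation
Z-scores, and the planted 5-gene prognostic cluster separates high- from
low-risk patients decisively on the held-out half of the cohort.

The same stages are available from the shell (`xtalk simulate`, `xtalk de`,
`xtalk coexpr`, `xtalk build`, `xtalk compare`, `xtalk keygenes`,
`xtalk dysreg`, `xtalk survival`, `xtalk run --config cfg.yaml`); real
studies supply TSV expression matrices with a sample→state map, a GMT
pathway file, a (regulator, target, type) GRN table and a
(sample, time, event) survival table.

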