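# diffcentral

Differential graph-centrality prioritization of cancer genes from paired
normal/tumor interaction subnetworks.

## What it does and for whom

Given a protein–protein interaction network `H`, per-patient expression
calls for paired normal and tumor samples, and per-tumor somatic mutation
calls, `diffcentral` builds for each patient `i` the induced subgraph pair

* `N_i` = `H` induced on the genes expressed in the normal sample,
* `T_i` = `H` induced on the genes expressed *and not non-silently mutated*
  in the tumor sample,

and ranks every gene `v` in the node universe `V = ∪_i (V_{N_i} ∪ V_{T_i})`
by how much its topological role differs across the pairs. It is aimed at
computational biologists who want a transparent, fully reproducible
network-differential baseline for driver-gene prioritization and a harness
to evaluate it.

Eight measures are implemented. The *unlabeled* ones accumulate absolute
per-graph centrality differences (large = interesting, ranked descending):

    W_x(v) = Σ_i | x_{N_i}(v) − x_{T_i}(v) |,   x ∈ {bw, cc, deg1, deg2}

with `bw` normalized betweenness, `cc` the clustering coefficient, `deg1`
the degree and `deg2` the second-order neighborhood size. The *labeled* ones
compare node-identified structure (low similarity = interesting, ranked
ascending): Pearson correlation of a gene's column in per-graph random-walk
or shortest-path proximity matrices (`m_rw`, `m_gt`), and Jaccard overlap of
its first/second-order neighborhoods (`m_j1`, `m_j2`). Two controls — the
expression difference `ed` and the mutation frequency `mf` — calibrate what
network topology adds. Rankings can be compressed with a greedy
maximum-weight-independent-set filter (GWMIN2) that removes
guilt-by-association redundancy, and evaluated with top-k% ROC/PR sweeps,
GO-consistency scores, and a network-rewiring robustness experiment.
`docs/methods.md` has the full model description.

## Worked example

Everything runs on seeded synthetic data (no downloads). The snippet builds
a 200-gene scale-free interactome with 6 planted drivers across 10 paired
samples, scores the betweenness measure, evaluates it against the planted
gold standard and filters the top 10 with GWMIN2:

```python
from diffcentral import (SyntheticConfig, generate_network, generate_instances,
                         build_instance_set, roc_pr_sweep, filter_ranking)
from diffcentral.measures import compute_measure

cfg = SyntheticConfig(n_genes=200, n_instances=10, n_drivers=6, seed=7)
H = generate_network(cfg)
instances, drivers = generate_instances(cfg, H)
pairs = build_instance_set(H, instances)

m_bw = compute_measure("m_bw", pairs)
curve = roc_pr_sweep(m_bw.ranking(), drivers, pairs.universe)
print(f"m_bw AUROC {curve.auroc:.3f}  AUPR {curve.aupr:.3f}")

report = filter_ranking(m_bw, H, top_n=10)
print(report.table[["rank", "gene", "weight", "in_mwis", "mwis_neighbors"]]
      .to_string(index=False))
print("planted drivers:", " ".join(drivers))
```

Output:

```
m_bw AUROC 0.978  AUPR 0.686
 rank gene   weight  in_mwis mwis_neighbors
    1 G164 1.831522     True
    2 G008 0.976834    False      G164,G177
    3 G130 0.936322    False           G164
    4 G178 0.881164    False           G164
    5 G004 0.787065     True
    6 G109 0.668051     True
    7 G119 0.603932    False      G164,G177
    8 G160 0.595793    False           G004
    9 G177 0.594639     True
   10 G001 0.548124    False           G177
planted drivers: G164 G008 G130 G001 G119 G186
```

Reading it: the AUROC of 0.978 says the betweenness differential ranks the
six planted drivers almost perfectly among 200 genes. In the filtered head,
`in_mwis=True` rows survive the independent-set filter; a `False` row lists
the surviving interaction partners that explain it away — e.g. drivers
`G008`, `G130` and `G119` are filtered because they interact with the
top-ranked driver `G164`, exactly the guilt-by-association compression the
filter exists for (the weight of the kept set still carries the heuristic's
provable lower bound).

The same pipeline is available from the shell:

```
diffcentral simulate --out data --n-genes 200 --n-instances 10 --seed 7
diffcentral score --network data/network.tsv --expression data/expression.tsv \
    --mutations data/mutations.tsv --measures m_bw,m_deg1,ed,mf --out rank
diffcentral mwis --measure-file rank/m_bw.tsv --network data/network.tsv \
    --gold data/gold.txt --top 50 --out report.tsv
diffcentral evaluate --ranking rank/m_bw.tsv --gold data/gold.txt \
    --obo data/toy.obo --gaf data/toy.gaf --out eval
diffcentral rewire-eval --network data/network.tsv --expression data/expression.tsv \
    --mutations data/mutations.tsv --gold data/gold.txt --ratios 5,10,15,20 \
    --replicates 4 --out rewired
```

Each command writes TSV artifacts plus a `manifest.json` (config, seeds,
input digests) sufficient to reproduce the run bit for bit.

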