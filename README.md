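# guildnet

Network ecology for microbiome cohorts: compositionally robust
co-occurrence inference (SparCC), guild/module decomposition, per-sample
network topology, and association of network features with clinical
indicators — built for longitudinal gut and oral metagenome studies around
kidney failure and transplantation, and usable for any cohort whose data
arrive as taxon×sample and KO×sample abundance tables.

## Why networks

Relative abundances are compositions: when one taxon's fraction rises the
others must fall, so naive correlations between taxa are biased negative.
SparCC estimates latent ("basis") correlations from log-ratio variances
t_ij = Var[log(x_i/x_j)], which are invariant to the closure, by solving

    sum_j t_ij ≈ (D−2)·w_i + sum_j w_j ,    rho_ij = (w_i + w_j − t_ij) / (2√(w_i w_j))

under the assumption that most basis correlations are near zero, with
iterative exclusion of strongly correlated pairs. Significant, strong
edges (|ρ| > 0.7, BH FDR < 0.05 by permutation bootstrap) form a
co-occurrence network; its densely connected modules ("guilds") and the
topology of each sample's induced subnetwork — modularity Q, mean degree,
linkage density, mean eigenvector centrality — become per-sample features
that can be correlated with blood biochemistry or fed to a random forest
predicting eGFR (CKD-EPI).

A synthetic-cohort generator (log-normal basis with planted correlation
blocks → composition → multinomial counts, plus trended cohort attributes,
coupled KO tables, and clinical indicators with known coefficients)
provides ground truth for every stage, so the whole chain is testable by
recovery.

## Worked example

```python
import numpy as np
from guildnet import (CovarianceSpec, simulate_counts, to_relative,
                      prevalence_abundance_filter, run_sparcc, edge_filter,
                      build_network, detect_modules, sample_network_properties,
                      module_relative_abundance)

# 30 taxa carrying four planted guilds (blocks of 8/8/7/7, within-block r=0.8)
spec = CovarianceSpec(n_taxa=30, module_sizes=[8, 8, 7, 7], within_r=0.8)
counts, truth = simulate_counts(spec, n_samples=500, depth=100_000,
                                zero_inflation=0.0, seed=11)

rel = prevalence_abundance_filter(to_relative(counts))   # >70% occurrence, >0.001% mean
result = run_sparcc(counts, n_resamples=20, n_bootstrap=100, seed=11)
edges = edge_filter(result, r_threshold=0.7, q_threshold=0.05)
g = build_network(edges, result.feature_ids)
part = detect_modules(g)

print(len(edges), sorted(part.major_labels.values()), round(part.modularity, 3))
stats = sample_network_properties(g, to_relative(counts))
print(stats[["mean_degree", "linkage_density", "centrality"]].mean().round(3))
```

Output:

```
98 ['M1', 'M2', 'M3', 'M4'] 0.745
mean_degree        6.533
linkage_density    0.218
centrality         0.267
dtype: float64
```

All 98 planted within-block pairs survive the |ρ| > 0.7 & q < 0.05 edge
rule and no spurious cross-block edge does, so module detection recovers
the four planted guilds exactly (labels M1–M4 go to modules holding >10%
of the nodes, by size; Q = 0.745 is the modularity of that partition).
The per-sample subnetwork statistics summarise each sample's share of the
network: with no structural zeros every taxon is present everywhere, so
each sample reproduces the global topology — mean degree 6.53 edges per
taxon, linkage density = mean degree / 30 nodes = 0.218, and mean
max-normalised eigenvector centrality 0.267 (centrality concentrates in
the largest module; the others' members score lower).

The same stages are available from a shell:

```bash
guildnet simulate --spec cohort.yaml --seed 11 --out sim/
guildnet sparcc --in sim/taxa.tsv --seed 11 --out sp/
guildnet network --edges sp/edges.tsv --nodes sp/nodes.txt --out net/
guildnet props --edges sp/edges.tsv --nodes sp/nodes.txt --table sim/taxa.tsv --out props.csv
guildnet diversity --table sim/taxa.tsv --metadata sim/metadata.csv --out div/
guildnet rf-egfr --features props.csv --clinical clinical.csv --out rf.json
guildnet egfr --age 40 --sex male --creatinine 0.9 --unit mg/dL   # -> 110.7
```

All outputs are plain text (TSV/CSV/JSON/GraphML) and byte-identical when
re-run with the same seed.

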