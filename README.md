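# pmenet

Microbial co-occurrence network analysis with random-matrix-theory (RMT)
threshold selection — from ASV count tables to signed phylogenetic
molecular ecological networks (pMENs), topology summaries, keystone-node
classification, degree-preserving null models, and between-network
comparisons.

## The problem

Amplicon surveys of complex communities (here: freshwater sediments
incubated under aeration vs. anaerobic control, sampled over three depth
layers and five time points) produce ASV-by-sample count tables.  Pairs
of taxa whose abundances co-vary across samples — positively or
negatively — form a co-occurrence network whose architecture (size,
connectivity, modularity, keystone nodes) summarizes how the community is
organized and how it responds to perturbation.

The crux of network inference is the correlation cutoff.  `pmenet`
selects it spectrally: for each candidate threshold *t*, the thresholded
Spearman matrix's eigenvalue *nearest-neighbor spacing distribution*
(NNSD, after unfolding to unit mean spacing) is tested against the
Poisson form P(s) = e^(−s).  A dense random background produces
Gaussian-orthogonal-ensemble statistics (Wigner surmise, level
repulsion); once the threshold prunes the random couplings and only
system-specific modules remain, the spacings turn Poisson.  The selected
threshold is the smallest *t* whose Poisson acceptance is stable (holds
at the next testable cutoff too).

## The pipeline

1. **Preprocess** (`pmenet.abundance`): rarefy each sample to a common
   depth (default 48,000 reads, hypergeometric subsampling), drop ASVs
   below 0.001% pooled relative abundance, keep ASVs present in more
   than half of the selected samples.
2. **Correlate** (`pmenet.correlation`): tie-aware Spearman's rho
   (Pearson of midranks) across all retained ASV pairs.
3. **Threshold** (`pmenet.rmt`): scan t = 0.01 … 0.95 in steps of 0.01,
   unfold each spectrum, chi-square-test the NNSD against Poisson; pick
   the threshold automatically, or fix it (e.g. 0.83) for cross-network
   comparability.
4. **Build & summarize** (`pmenet.topology`): signed network over
   |rho| ≥ t; power-law R² of the degree distribution, average
   connectivity (2L/N), positive-link proportion, average path length
   (connected pairs), average clustering, greedy (Clauset–Newman–Moore)
   modularity M.
5. **Classify roles** (`pmenet.roles`): within-module degree z-score Zi
   and participation coefficient Pi = 1 − Σ_t (k_it/k_i)²; peripherals
   (Zi ≤ 2.5, Pi ≤ 0.62), module hubs (Zi > 2.5), connectors
   (Pi > 0.62), network hubs (both).  Non-peripherals are keystones.
6. **Null models** (`pmenet.nulls`): Maslov–Sneppen double-edge-swap
   ensembles preserving every node's degree; metric mean ± sd and
   z-scores.
7. **Compare** (`pmenet.compare`): shared-node percentages (of the node
   union), relative percent changes of metrics, taxon-anchored
   first-neighbor subnetworks (e.g. family *Desulfobulbaceae*).

A planted-structure generator (`pmenet.synthetic`) emulates the
2 groups × 5 weeks × 3 layers × 6 replicates design with known module
membership, pair signs and hub nodes, so the whole pipeline is testable
without sequencing data.

## Worked example

```python
from pmenet import (SyntheticSpec, generate_planted_community, spearman_matrix,
                    scan_thresholds, select_threshold, build_network,
                    greedy_modules, classify_roles, keystone_census,
                    topology_summary, null_summary)

spec = SyntheticSpec(n_modules=4, module_size=20, n_background=80,
                     rho_in=0.85, rho_out=0.05, depth=10_000, seed=0)
table, truth = generate_planted_community(spec)

corr = spearman_matrix(table)
t = select_threshold(scan_thresholds(corr), mode="auto")
net = build_network(corr, t, taxonomy=table.taxonomy, label="demo")
modules, modularity = greedy_modules(net)
records = classify_roles(net, modules)
summary = topology_summary(net, modules, modularity)
null = null_summary(net, n_random=20, swaps_per_edge=10, seed=0,
                    modules=modules, modularity=modularity)
```

prints (via the obvious `print` statements):

```
160 ASVs x 180 samples
RMT threshold: 0.22
network: 121 nodes, 815 links, avgK=13.47, positive=63.1%, M=0.680 (13 modules)
null modularity: 0.183 ± 0.038 (z = 13.1)
```

The scan rejects Poisson while the dense sampling-noise background is
still coupled and accepts it from t = 0.22, below the weakest planted
within-module correlation — so the four planted modules come out intact
(module NMI ≈ 1.0 against ground truth), with the negative links
arising from the planted anti-correlated loadings, and an empirical
modularity 13 standard deviations above its degree-preserving null.

Role classification on a deterministic fixture with one planted
intra-module super-hub and one three-module broker:

```python
from pmenet import generate_toy_role_graph
net, expected = generate_toy_role_graph()
```

```
census: {'peripheral': 36, 'module_hub': 1, 'connector': 1, 'network_hub': 0, 'keystone': 2}
HUB: Zi=3.46 Pi=0.000 -> module_hub
BRK: Zi=-2.68 Pi=0.656 -> connector
```

## Command line

```sh
pmenet simulate --out data/ --seed 0            # synthetic tables + ground truth
pmenet scan  --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
             --metadata data/metadata.tsv --out scan.tsv
pmenet build --counts data/counts.tsv --taxonomy data/taxonomy.tsv \
             --metadata data/metadata.tsv --where group=aeration \
             --threshold-mode auto --out net/
pmenet null  --network net/network.graphml --out null.json
pmenet compare net_a/network.graphml net_b/network.graphml --out cmp/
pmenet run   --config config.yaml               # full multi-group pipeline
```

Networks are written as GraphML plus Cytoscape-importable node/edge
TSVs; every run emits a manifest with all resolved parameters and seeds.

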