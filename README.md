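# kmernet

Sequence composition and sequence similarity in promoter–enhancer
interaction networks, analysed through k-mer counts.

Capture Hi-C experiments yield maps of physical contacts between
promoters (bait regions around transcription start sites) and distal
enhancer regions. Treating regions as nodes and contacts as edges gives
a bipartite graph in which the **node degree** — the number of distinct
partners a region interacts with — becomes a property one can relate to
the underlying DNA sequence. `kmernet` implements that analysis for
researchers in regulatory genomics:

* **k-mer count vectors.** Every region is standardized to a 1 kb
  window (centered on the TSS for promoters, on the fragment midpoint
  for enhancers) and described by the vector of overlapping k-mer
  counts on the + strand (k = 4 → 256 coordinates, no
  reverse-complement folding).
* **k-mer distance and lakd.** Sequence dissimilarity of an interacting
  pair is the Euclidean distance ‖**c**ₚ − **c**ₑ‖ of their count
  vectors. The *local average k-mer distance* (lakd) of a node is the
  mean k-mer distance over its incident edges — per-promoter in one
  grouping, per-enhancer in the other — and its distributions and
  degree trends (OLS slope, Spearman ρ, two-sample
  Kolmogorov–Smirnov comparison) quantify which side of the network is
  locally more similar to its partners.
* **Degree profiles and clustering.** For each k-mer, its mean count at
  node degrees 1–10 is computed per node type; promoter and enhancer
  profiles are joined head-to-tail (length 20), centered, and clustered
  with PAM k-medoids, the number of clusters selected by the gap
  statistic. Clusters are annotated with their CpG/GC content and the
  monotonicity of their median profiles.
* **Composition trends.** GC% and the four G/C dinucleotides (GG, CC,
  GC, CpG) per region, their correlation and OLS slope against node
  degree, and per-degree fold changes relative to degree 1.
* **Synthetic data.** A seeded generator produces a bipartite network
  (broad promoter degree law, mostly degree-1 enhancers, configuration
  model wiring) and first-order Markov sequences whose GC propensity
  rises with node degree and whose CpG density is damped per node type,
  so the entire pipeline runs and is tested without any downloads.

Real interaction tables are read from a documented generic TSV dialect,
or via thin adapters for Excel supplementary tables (1-based
coordinates) and BED-style contact files (0-based), with user-supplied
column maps; genomes are read from FASTA.

## Worked example

```bash
kmernet simulate --out demo --seed 20210728
kmernet report --input demo/interactions.tsv --genome demo/genome.fa \
    --seed 20210728 --out demo/results
```

The `report` subcommand chains `count → profile → cluster → lakd →
trends` and prints, among other things, the lakd degree-trend table:

```
grouping     slope       slope_p  spearman_rho    spearman_p    n
promoter  2.062786 5.299986e-148      0.876837 1.016485e-112  350
enhancer -1.207228  4.022144e-03     -0.012539  6.107652e-01 1650
```

Read: with the default generator settings (350 promoters averaging ~6
partners, 1,650 mostly degree-1 enhancers, promoter GC propensity 0.55
vs enhancer 0.45, both rising 0.01 per unit degree), a promoter's lakd
*increases* by ~2.1 distance units per unit degree (higher-degree
promoters grow less similar to their enhancers), while an enhancer's
lakd *decreases* (higher-degree enhancers grow more similar to
promoters) — the directional asymmetry the statistic is designed to
expose. `demo/results/` additionally contains the k-mer vectors,
ranked mean-count tables, cluster assignments and gap curve,
edge-degree grids, composition trend tables, and a JSON manifest per
stage recording parameters, seeds and input hashes.

Python API equivalents live in `kmernet.*` (see module docstrings);
the CLI is a thin wrapper.

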