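# Methods

## The analysis model

The object of study is a bipartite graph G = (P ∪ E, I): promoters P,
enhancers E, interactions I ⊆ P × E. Exact duplicate pairs are
collapsed on input (an interaction count is a count of unique pairs;
`--keep-duplicates` preserves multiplicity for sensitivity checks).
The degree deg(v) of a node is its number of distinct partners.

Every region is reduced to a fixed window of w = 1000 bp (configurable,
must be even) centered on an anchor: the TSS for promoters, the
midpoint ⌊(start+end)/2⌋ for enhancers. Windows running past a
chromosome end, or on a chromosome absent from the FASTA, are dropped
(not clipped) so that all k-mer vectors describe sequences of equal
length; drops are counted and the affected nodes are removed from the
network together with their edges before any edge statistic is
computed. Sequences are always read from the + strand; a promoter's
strand locates its TSS but never triggers reverse complementation,
because counts of a k-mer and of its reverse complement are kept as
separate coordinates throughout.

**k-mer vectors.** For a window s and k = 4 (default), c(s) ∈ ℕ^256
counts the overlapping k-mers of s in lexicographic order (A<C<G<T).
Windows containing a non-ACGT character contribute to no k-mer — they
are skipped entirely rather than partially matched, the convention of
canonical-off k-mer counters; with no ambiguous bases the counts sum to
w − k + 1. k is capped at 8 (vector length 65,536).

**k-mer distance and lakd.** d(p, e) = ‖c(p) − c(e)‖₂ for an
interacting pair. The local average k-mer distance of a node v is

    lakd(v) = (1 / deg v) · Σ_{(v,u) ∈ I} d(v, u),

i.e. the same edge set averaged per promoter or per enhancer. The two
groupings obey an exact conservation identity used as a test: the
degree-weighted mean of lakd over promoters, the degree-weighted mean
over enhancers, and the plain mean of all edge distances coincide
(each edge contributes once to each side). Distribution asymmetry
between the groupings is measured by the two-sample Kolmogorov–Smirnov
statistic with the asymptotic p-value (effective n = n₁n₂/(n₁+n₂));
the sample sizes here make small-sample exact p-values unnecessary.

**Degree trends.** Trends of lakd or of a composition metric against
degree are computed over individual nodes, not per-degree means: an
ordinary least-squares slope with its p-value, and the Spearman rank
correlation with average ranks for ties. Node-level regression is the
default unit of analysis because it reflects the actual sample size
(thousands of nodes); per-degree means are reported alongside for
plotting. The degree range is unrestricted by default and configurable.
The correlation column of the composition trend table is Spearman by
default with a `pearson` switch for sensitivity; the choice is logged.

**Composition metrics.** gc_percent = 100·(#G+#C)/(#A+#C+#G+#T)
(ambiguous bases excluded from the denominator; an all-N window is
dropped), plus overlapping counts of GG, CC, GC and CG, the latter
meaning C immediately followed by G in 5′→3′ orientation. Fold change
at degree d is mean(d)/mean(1), exactly 1 at degree 1; absence of
degree-1 nodes is an error rather than a silent NaN.

**Degree profiles and clustering.** For each k-mer and node type, the
profile value at degree d ∈ {1..10} is the mean count over exactly the
nodes of that type and degree (degree cap configurable; nodes above
the cap stay in the network but not in profiles). The promoter and
enhancer profiles of a k-mer are concatenated promoter-first and
centered by subtracting the joint mean, restricted to the degrees
populated in *both* types (an empty degree is logged and excluded).
The 256 centered vectors are clustered with PAM k-medoids under
Euclidean distance: one greedy BUILD start plus seeded random restarts,
each descending by best-improvement SWAP exchanges until no
(medoid, non-medoid) swap lowers the cost Σᵢ d(xᵢ, m(xᵢ)). The swap
phase matters: Lloyd-style alternation (assign, then re-center within
clusters) cannot split two medoids that initialize inside the same
tight cluster, and measurably fails on well-separated data.

The number of clusters is selected by the gap statistic:
Gap(k) = E*[log W_k] − log W_k with W_k the k-medoids cost, the
reference expectation over B = 50 sets drawn uniformly over the
per-coordinate range of the data (the simpler reference, without PCA
rotation), and k* the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1},
where s_k inflates the reference standard deviation by √(1+1/B). If no
k satisfies the rule, k_max is returned with a warning.

Clusters are annotated with member counts of CpG-containing, GC-only
and AT-only k-mers and with a monotonicity label: the Spearman ρ of
the median promoter half and median enhancer half against degree,
labelled increasing/decreasing when both halves agree at |ρ| ≥ 0.5,
flat when both are below threshold, mixed otherwise. The threshold is a
labelling convention for qualitative cluster description, not a
hypothesis test. The association between CpG content and
degree-increasing profiles is tested with a one-sided Fisher exact
test on the 2×2 table (membership in increasing vs decreasing
clusters) × (CpG-containing vs not).

## The synthetic generator

The generator emulates the statistical structure of a capture Hi-C
promoter–enhancer dataset, scaled to run in seconds:

* **Degrees.** Promoters: zero-truncated negative binomial, default
  mean 6 and dispersion 2 (real promoter–enhancer maps show promoters
  averaging ~6 partners with a long tail). Enhancers: degree 1 with
  probability p₁ = 0.8, otherwise 1 + Geometric(0.6) (most enhancers
  contact a single promoter; realized mean ≈ 1.33). Defaults
  n_promoters = 350, n_enhancers = 1650 keep the real ~4.5 : 1
  enhancer:promoter ratio at ~2,000 nodes total.
* **Stub reconciliation.** The two degree sequences must have equal
  totals to be wired. The side with fewer stubs is redrawn by rejection
  until its total matches the other side's — exact conditioning on the
  sum, which leaves each node's degree with the law's conditional
  distribution (verified by χ² goodness of fit at n = 58,000). If the
  laws' expected totals are structurally incompatible, a gap-shrinking
  resampling pass and finally unit increments close the gap; both are
  logged as law distortions.
* **Wiring.** Configuration model: degree-many stubs per node, a
  seeded permutation pairs them. Duplicate edges are broken by random
  endpoint swaps (up to 1,000 rounds); irreducible duplicates are
  dropped with a warning, keeping the graph simple like the
  deduplicated real data.
* **Sequences.** Each node receives its own synthetic chromosome of
  w + 2·pad bases (pad = 100) from a first-order Markov chain over
  {A,C,G,T}. The chain's target GC propensity is
  g = clip(g_base(type) + 0.01·(deg − 1), 0.05, 0.95) with
  g_base = 0.55 for promoters and 0.45 for enhancers; each row of the
  transition matrix puts (1−g)/2 on A and T and g/2 on C and G, then
  the C→G entry is multiplied by a per-type CpG-depletion factor
  (0.8 promoters, 0.3 enhancers — enhancers are strongly CpG-depleted)
  and the C row renormalized. The initial base is drawn from the
  undepleted distribution. Because the depletion rescales one row, the
  realized stationary GC fraction sits slightly below g, more so for
  enhancers; g is the *target propensity*, and the truth table records
  it per node for recovery tests (measured GC% correlates with g at
  r ≈ 0.98 over 2,000 nodes).
* **Seeding.** All randomness flows from one seed through named
  substreams (degrees, wiring, sequences), with each node's sequence
  stream additionally indexed by the node, so any stage can be
  regenerated independently.

What the generator does *not* emulate: real base composition beyond
first order (no repeats, isochores or CpG islands as entities), genomic
distance between partners, assay noise, or multiple TSSs per gene.
Passing tests therefore demonstrate that the pipeline's statistics
recover planted composition–degree structure and respect exact
identities — not that any particular biological dataset shows these
effects.

Why the planted structure reproduces the qualitative lakd asymmetries:
promoters are GC-richer than enhancers, and both get richer with
degree, so a high-degree promoter is compositionally farther from its
(mostly degree-1, GC-poor) enhancers — promoter-grouped lakd rises
with degree — while a high-degree enhancer approaches promoter
composition — enhancer-grouped lakd falls. Those opposite node-level
trends in turn force the unweighted promoter lakd distribution below
the unweighted enhancer distribution, since the degree-weighted means
of both groupings are pinned to the same edge-distance mean by the
conservation identity.

## Numerical and design choices

* Coordinates are 0-based half-open internally; the generic TSV
  dialect is documented as 0-based, while the Excel adapter converts
  from 1-based inclusive and BED input is already half-open.
* Ties in k-mer rankings break lexicographically; PAM restarts and the
  gap reference draws are fully seeded, so every clustering result is
  reproducible bit-for-bit from its manifest.
* W_k in the gap statistic is the k-medoids cost itself (sum of
  unsquared distances to medoids) — the dispersion the clusterer
  actually minimizes; k_max is clamped below the number of points, and
  log W uses a 1e-300 floor against degenerate zero-cost fits.
* TSV output serializes NaN as `NA` and floats at 10 significant
  digits, which round-trips all statistics to within 1e-9.
* Problem sizes in the test-suite and acceptance runs: the full
  pipeline runs on the default ~2,000-node dataset; degree-law
  goodness-of-fit uses one 58,000-node network per seed; the null
  (zero-slope) calibration uses 20 seeds at 2,000 nodes each. These
  sizes give the trend tests overwhelming power on planted effects
  while keeping a complete run around a minute.

## Known limitations

* The Excel and BED interaction dialects need a user-supplied column
  map; published supplementary tables have no standard schema, and
  guessing one silently would be worse than asking.
* The gap statistic on real 256-profile data may select a different
  cluster count than other k-medoid implementations (reference
  distribution and dispersion definitions vary between
  implementations); the cluster *annotations* (CpG composition vs
  trend direction) are the stable output, not the cluster count.
* The pipeline models unweighted degree only; contact-frequency
  weighting is deliberately out of scope.
* lakd is undefined for isolated nodes (possible after out-of-bounds
  drops); they are skipped and logged rather than imputed.
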