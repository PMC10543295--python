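# Methods

## Problem setting

Regional biobanks oversample relatives, so participants who co-inherited a
chromosomal region from a recent common ancestor share it identical by
descent (IBD). A rare pathogenic variant present in that ancestor travels
with the surrounding haplotype: among people whose IBD segments *span* the
variant's locus, carriers of the founder haplotype form a tightly
interconnected sharing group. `ibdcluster` takes pairwise IBD segments
(as produced by a phased detector such as hap-IBD), selects the segments
spanning a target locus, and partitions the sharing haplotypes into
clusters that behave like extended families — candidate carrier groups
that can be prioritized for sequencing when anchored by known carriers.

Upstream steps (genotyping QC, phasing, IBD detection) and downstream
steps (pedigree reconstruction, sequencing validation, phenotype
association) are out of scope.

## Segment selection and graph assembly

A segment spans the locus when its physical interval fully contains the
target interval on the same chromosome; full containment is required
because only a segment covering the whole locus carries its complete local
haplotype (an any-overlap mode exists but is not the default). Retention
additionally requires genetic length strictly greater than `min_cm`
(default 3 cM), the conventional noise floor below which detected segments
are increasingly erroneous.

Nodes of the sharing graph are haplotypes — `(sample, hap index)` pairs —
not individuals, because IBD is a property of a single parental chromosome
copy. Collapsing to individuals happens only in reporting. When a pair of
haplotypes has several spanning segments, the longest is kept (ties keep
the first seen): the strongest evidence of co-inheritance. The edge weight
is that segment's length in cM.

## Random-walk clustering

Clusters are found with a deterministic Pons–Latapy walktrap:

* **Walk model.** Transition probabilities are proportional to edge
  weights, so a short random walk started inside a family tends to stay
  inside it. The walk is *lazy*: each node carries a self-loop of weight
  equal to its weighted degree, giving a staying probability of 1/2. This
  follows the canonical walktrap implementation and matters even on small
  graphs — without laziness, odd/even parity effects of short walks can
  make a bridge edge look closer than a within-clique edge.
* **Walk length** t = 3 (configurable). Three steps probe the
  neighborhood at the scale of close-family cliques without diffusing
  across weak bridges.
* **Community distance.** r²(C₁,C₂) = Σₖ (Pᵗ_{C₁k} − Pᵗ_{C₂k})²/d(k),
  with Pᵗ_C the mean t-step profile of C's members and d the (lazy)
  weighted degree. Adjacent communities are merged agglomeratively,
  always the pair minimizing the walktrap merge cost
  Δσ = |C₁||C₂|/(n(|C₁|+|C₂|)) · r².
* **Cut criterion.** The merge dendrogram is cut at the level of maximum
  *unweighted* (topological) modularity, computed per connected component.
  Lengths decide the walk and merge order; connectivity alone decides
  where a cluster ends. This is a deliberate design choice: close
  relatives share an order of magnitude more cM than distant cousins
  (siblings ~100 cM around the locus versus ~15 cM at ten meioses), so a
  length-weighted modularity cut shears topologically complete extended
  families along their strong sibling edges. With the topological cut, a
  family whose members all share spanning segments — a clique in the graph
  — is never split, while groups of cliques joined by single weak bridges
  are separated exactly (verified against brute-force modularity
  enumeration on all connected graphs with ≤ 7 nodes whose unique optimum
  has that clique-union structure).
* **Determinism.** There is no sampling anywhere ("random" refers to the
  walk model). Ties in the merge order are broken by the lexicographically
  smallest member of each community; ties in the cut level resolve to the
  most merged level. Identical inputs give byte-identical outputs.

Complexity is O(n³) per connected component in this dense-matrix
implementation, which is comfortable for the per-locus component sizes the
tool targets (tens to a few thousand haplotypes); it is not a genome-wide
all-pairs engine.

### Refinement of large, sparse clusters

Spurious chains of weak links can glue families together. Any cluster that
is simultaneously **large** (more than `max_size` = 30 members) and
**sparse** (fewer than `min_density` = 50% of member pairs joined by a
retained edge) is re-clustered on its induced subgraph, for at most
`max_refine_iter` = 5 rounds. Both gates must fail: a large dense cluster
is a credible extended family, and a small sparse one is left to the
reporting thresholds. A qualifying cluster the walktrap cannot split is
kept intact with the round counted; a cluster still failing both gates
when the cap is reached is reported with `converged = false`. Clusters
with fewer than `min_cluster_size` = 3 members are logged but dropped from
reports.

## Cluster diagnostics

Per cluster: haplotype count, individual count (distinct sample ids),
connected-pair percentage (100 × retained edges / C(n,2)), and the mean
retained edge length in cM. Percentages and means are rounded half-up to
one decimal, matching conventional reporting precision. Distant
relatedness *between* two clusters is quantified by counting IBD segments
longer than `cross_cluster_min_cm` = 1 cM joining an individual of one to
an individual of the other, anywhere in the genome — such segments are
typically too short to pass the spanning filter, which is precisely why
they are informative about older shared ancestry. A `span_only` mode
restricts the count to locus-spanning segments.

## Dendrograms

Within a cluster, the local familial distance of a pair is the inverse of
their shared spanning length (1/cM): longer sharing, more recent common
ancestor, smaller distance. Taxa default to individuals (using the best
haplotype pair); a haplotype-level mode exists. Pairs with no retained
segment are imputed at twice the largest observed distance — tree building
needs a complete matrix, and doubling the maximum keeps imputed pairs
outermost without distorting observed structure; imputed pairs are flagged
and logged.

Trees are built by classic neighbor joining (default; exact on additive
matrices, deterministic with first-minimum tie-breaking) or by balanced
minimum evolution: NJ starting topology, greedy nearest-neighbor
interchanges minimizing the Pauplin length Σ d_ij 2^(1−p_ij), and ordinary
least-squares branch lengths. Negative branch lengths (possible for both
NJ and OLS on non-additive input) are clamped to zero with a warning.
Newick output carries branch lengths at six significant digits and quotes
labels containing metacharacters.

## Recombination-clock allele age

Under a star genealogy — every carrier pair coalescing in the founder T
generations back — the shared segment around the variant is truncated by
recombination on two independent lineage paths of T meioses each. With
Haldane's no-interference model each one-sided extent is Exp(2T) per
Morgan, so a pair's spanning length L is Gamma(shape 2, rate 2T). For n
pairs the maximum-likelihood estimate is T̂ = 100·n / Σ Lᵢ[cM], and
because 2T·ΣLᵢ ~ Gamma(2n, 1) is an exact pivot, the equal-tailed 95%
interval is [q₀.₀₂₅/(2S), q₀.₉₇₅/(2S)] with S in Morgans.

Assumptions and their consequences:

* **Star genealogy.** Real carrier pairs coalesce below the founder, so
  pair TMRCAs are smaller than T and the estimate is a lower-bound-leaning
  simplification; it shares the clock principle, not the machinery, of
  full genealogical age estimators that combine recombination and
  mutation clocks against a reference panel.
* **Independence.** Overlapping pairs from one cluster are correlated;
  `select_disjoint_pairs` greedily subsamples pairs using each individual
  once for a conservative alternative.
* **No end truncation.** Valid while 100/T is much shorter than the map; a
  warning is emitted when any segment exceeds 25% of a supplied map
  length.

## Synthetic data

The simulator emulates exactly the structure the clustering assumes. A
founder carries the variant on haplotype 1 with the full chromosome as its
retained interval. Each generation, every carrier has Poisson(`offspring_mean`)
children, each inheriting the variant with probability 1/2; a transmitting
meiosis draws Poisson(`chrom_len_cm`/100) crossovers uniformly on the
chromosome (Haldane, no interference) and intersects the parent's retained
interval with the crossover-free interval around the variant. A carrier
pair's IBD segment is the exact intersection of their retained intervals —
no resampling drift, so emitted lengths satisfy the same exponential-
extent theory the age clock is tested against (mean one-sided extent
100/m cM after m meioses). Background noise adds `n_noise_pairs` segments
with Exp(`noise_mean_cm`) lengths, uniformly placed, between random
members of a non-carrier pool (one pool member per requested pair, with a
floor of two; noise lengths are floored at 0.01 cM so physical rounding
cannot produce degenerate intervals). Physical coordinates use a uniform
map: bp = round(cM/`cm_per_mb` × 10⁶) + 1.

Defaults — 6 generations, mean 2.5 offspring (carrier-lineage branching
factor 1.25), a 150 cM chromosome with the variant at its center, 200
noise pairs of mean 2 cM — describe a regional founder event a few
centuries old observed through a biobank-scale IBD scan: deep enough for
meaningful segment attrition, shallow enough that carrier sharing stays
above the 3 cM filter.

What the simulator does **not** model: genotyping and phasing error
(including switch errors that fragment segments), marker-density limits on
detectable segment length, interference, variable recombination maps,
non-carrier background relatedness beyond the noise pairs, and mating
between lineage members. Passing recovery tests therefore shows the
pipeline is correct under its own generative assumptions, not that real
biobank IBD is this clean; in real data, detection error mainly removes
edges, which the density diagnostics and refinement gates are there to
absorb.

The deterministic worked-example fixture is a 21-member group (7 clinic
ids, 14 biobank ids) in which exactly k of the 210 member pairs carry one
spanning segment longer than 3 cM, where k is found by scanning all k for
the unique value whose percentage rounds half-up to 82.9% (k = 174).
Connected pairs are the first 174 in lexicographic member order — which
keeps the graph connected, as every pair involving the first member is
included — and lengths sweep 3.10–19.99 cM by a fixed decorrelating rule
(3.1 + (97·i mod 1690)/100) so weight carries no block structure aligned
with member order. The pipeline reports it as a single 21-haplotype
cluster with connected-pair percentage 82.9%.

## Numerical and degenerate-input choices

* Threshold comparisons on segment length are strict (`> min_cm`).
* Percent/mean rounding is decimal half-up (not banker's rounding).
* Reported cluster ids are assigned by decreasing size, then smallest
  member; all member lists are sorted.
* Empty filtered graphs are a warning, not an error; the CLI exits 0 with
  empty outputs.
* Singleton clusters cannot be summarized (no pairs) and raise.
* A cluster mean with zero internal edges is reported as NA.
* Within-individual "IBD" rows (both sides the same sample) are rejected
  at parse time rather than silently interpreted.

## Test problem sizes

The property suites run at sizes chosen to make their oracles exact:
brute-force modularity enumeration covers all 995 connected graphs on ≤ 7
nodes (877 set partitions at n = 7); clique-union recovery uses 2–4
cliques of 5–20 nodes; refinement contracts use 100 random graphs of
20–60 nodes; NJ exactness uses 200 random additive trees of 4–8 taxa; BME
uses exhaustive search over all 105 six-taxon topologies; the age clock
uses 500 replicates of 200 pairs at T = 46; simulator calibration uses
10,000 meiosis chains for m ∈ {2, 5, 10} on a 1000 cM map (long enough
that end truncation is negligible).

## Known limitations

* The dense walktrap is per-locus; genome-wide scans should loop over loci
  externally.
* Cluster membership is hard (no overlapping communities), so an
  individual whose two haplotypes sit in different clusters appears in
  both at the individual level.
* The age clock's star-genealogy and independence simplifications make its
  interval honest only under its own model; treat it as an order-of-
  magnitude instrument.
* Coordinates are 1-based inclusive throughout, matching the hap-IBD
  dialect; no lift-over or half-open conversion is performed.
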