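# ibdcluster

Locus-focused clustering of identity-by-descent (IBD) segments for
founder-variant carrier inference.

Regional biobanks are full of cryptic relatives. People who co-inherited a
chromosomal region from a recent common ancestor share it identical by
descent, and a rare pathogenic variant present in that ancestor travels
with the surrounding haplotype. Given pairwise IBD segments from a phased
cohort (hap-IBD output dialect) and a target Mendelian-disease locus,
`ibdcluster` finds the groups of haplotypes that share a segment spanning
the locus — candidate carrier groups that can be anchored by known
carriers and prioritized for sequencing. It is aimed at statistical
geneticists working with biobank IBD scans.

## Method

1. **Segment selection.** Keep segments on the target chromosome whose
   interval fully contains the locus and whose genetic length exceeds
   `min_cm` (default 3 cM, strict).
2. **Sharing graph.** Nodes are haplotypes *(sample, hap)*; each retained
   pair gets one edge weighted by its longest spanning segment's length
   *w* (cM).
3. **Random-walk clustering.** A deterministic Pons–Latapy walktrap with
   lazy three-step walks, transition probabilities proportional to *w*.
   Communities at distance
   r²(C₁,C₂) = Σₖ (Pᵗ_{C₁k} − Pᵗ_{C₂k})² / d(k)
   are merged agglomeratively (minimum Δσ), and the dendrogram is cut at
   maximum topological modularity within each connected component —
   lengths drive the walk, connectivity decides where a family ends.
4. **Refinement.** Clusters that are both large (n > 30) and sparse
   (< 50% of member pairs connected) are re-clustered on their induced
   subgraph, up to five rounds.
5. **Diagnostics and trees.** Per cluster: connected-pair percentage and
   mean segment length; cross-cluster relatedness from short (> 1 cM)
   segments genome-wide; dendrograms from pairwise distances 1/*w*
   (neighbor joining, or balanced minimum evolution with NNI).
6. **Allele age.** Under a star genealogy the spanning length of a carrier
   pair is Gamma(2, rate 2T) in Morgans, giving the recombination-clock
   estimate T̂ = 100·n / Σ Lᵢ[cM] generations with an exact gamma-pivot
   confidence interval.

A founder-pedigree simulator (Poisson offspring, Haldane crossovers,
exact segment intersections, background noise pairs) generates matched
synthetic data with carrier truth tables. See `docs/methods.md` for
assumptions, parameter meanings, and limitations.

## Worked example

Simulate a six-generation founder pedigree with 200 background noise
segments, then cluster at the variant position (75 cM → bp 75,000,001):

```bash
ibdcluster simulate --seed 7 --out sim
ibdcluster cluster --ibd sim.ibd.tsv --target 1:75000001 --out run
cat run.clusters.tsv
```

```
cluster_id  n_haplotypes  n_individuals  density  mean_cm  converged  members
c1          11            11             100.0    60.5     true       F0:1,G1S1:1,G2S2:2,G2S3:2,G3S4:2,G3S5:2,G3S6:1,G4S7:2,G5S8:1,G6S10:2,G6S9:1
```

Every one of the 11 haplotypes is a true carrier from `sim.carriers.tsv`
(the founder F0 plus ten descendants); 100.0% of member pairs share a
spanning segment, averaging 60.5 cM — the signature of a close extended
family. The run summary (`run.summary.json`) echoes the configuration and
counts: 255 segments read, 58 spanning the locus, 4 clusters found, 1
reported (the noise pairs form two-member groups below the three-member
reporting floor).

A dendrogram and an allele-age estimate for the reported cluster:

```bash
ibdcluster tree --ibd sim.ibd.tsv --target 1:75000001 --out tr
ibdcluster age --lengths lengths.txt --map-length 150
```

`tr.c1.nwk` begins
`(G3S6:0.0208359,G6S10:0.0250731,((G4S7:0.00637651,G6S9:0.00637651):0,...`
— branch lengths are inverse shared cM, so sibling-like pairs sit close
together. With `lengths.txt` holding the cluster's 55 retained
spanning-segment lengths, the age command prints:

```json
{
  "ci_high": 1.9748394763422532,
  "ci_low": 1.3578477300693665,
  "conf": 0.95,
  "n_pairs": 55,
  "t_hat_generations": 1.652127320440983
}
```

T̂ ≈ 1.7 generations: most pairs in this small pedigree are close
relatives sharing very long segments, and the star-genealogy clock reads
the *pairwise* coalescent depth, not the founder's age — with a warning
(long segments exceed a quarter of the 150 cM map) flagging exactly this
regime. On lengths drawn from the clock's generative model the estimator
is well calibrated (see the test suite).

Known-carrier seeding: pass `--seeds carriers.txt --min-seeds 2` to report
only clusters containing at least two seed individuals.

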