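# Methods

`epitriclust` mines coherent (gene set × group set × mark set) patterns —
triclusters — from promoter-binned epigenetic signal across sample
groups (e.g. cancer types). This note documents the model, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## The pipeline

**Phase 1 — tensors.** Each promoter is partitioned into `n_bins`
contiguous bins of near-equal length (lengths differ by at most 1 bp;
the remainder goes to the earliest genomic bins). Bin order is
strand-aware: bins are reversed for `-` strand promoters so bin 1 is
always promoter-proximal, making profiles comparable across genes.
Signal records are attributed to bins fractionally, `value × overlap /
record_length`, which conserves mass exactly. Each group's slice is
depth-normalized linearly: every value is multiplied by
`target_total / library_total`, where the library size is the group's
full-track mass by default (a counts-per-million analogue when
`target_total = 1e6`). The result per mark k is a tensor
D_k ∈ R^(groups × genes × bins), non-negative and finite.

**Phase 2 — coherence transactions and biclusters.** For each gene and
mark, the Pearson correlation r is computed between every unordered pair
of group bin-profiles. Pairs with r ≥ θ (default θ = 0.65; a stricter
preset 0.72 is exposed — neither is privileged) become *items*; the item
set of one gene is its *transaction*. Zero-variance profiles carry no
trend evidence, so their pairs are excluded, never counted as coherent.
The threshold is closed (≥), avoiding knife-edge behaviour in tests.

Transactions are mined with FP-growth (prefix tree, header table,
recursive conditional pattern bases), implemented from scratch: items
below minimum support are dropped, insertion order is descending global
frequency with lexicographic tie-break, and every frequent itemset's
supporting gene set is recovered by one final scan that also
cross-checks the mined support count. Minimum support is
`ceil(fraction × n_genes)`, never below 1; the standard fraction is 10%
of studied genes. A brute-force subset-enumeration oracle (alphabet ≤ 20)
backs the miner in tests.

A frequent itemset of group-pairs is read back as a group *set* only
when its pairs form a complete graph over the groups they touch:
pairwise correlation is not transitive, so the clique is the
conservative reading of "groups sharing one pattern". Clique-consistent
itemsets become biclusters (mark, group set, supporting gene set);
a bicluster is dropped only when another has a superset group set AND a
superset gene set — incomparable biclusters are all kept. Two-group
biclusters are admitted (the minimal coherent unit, and Phase 3 needs
them).

**Phase 3 — triclusters.** Biclusters are intersected across marks:
all valid two-mark intersections (≥ 2 shared groups, ≥ min_support
shared genes) seed a breadth-first growth that adds one mark at a time,
re-intersecting group and gene sets. Intersection only shrinks sets, so
every prefix of a surviving candidate also survives; growth is therefore
complete and invariant to mark processing order. Candidates are
deduplicated by (marks, groups, genes) signature, with a cap
(default 10^5) that raises an explicit overflow error rather than
silently truncating. The final list is pruned to maximal triclusters
(dominated simultaneously in marks, groups and genes → dropped) and
canonically sorted by (|marks|, |groups|, support, labels), all
descending — "optimality" of a tricluster is not otherwise defined, so
the maximal set with this deterministic ranking is reported.

Every mined tricluster is re-verified directly against the tensors
(`verify_tricluster`): all within-group pairwise correlations for every
(gene, mark) member must reach θ. This decouples the correctness of the
output from the mining path.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_bins` | 10 | bins per promoter; no canonical value exists, 10 gives 8 df for the correlation |
| `theta` | 0.65 | coherence threshold on Pearson r; 0.72 preset for stricter profiles |
| `min_support_fraction` | 0.10 | minimum supporting-gene fraction |
| `target_total` | 1e6 | depth-normalization target (CPM analogue) |

## The synthetic world

`PlantedModel` emulates the structure the miner assumes: within a
planted (marks × groups × genes) block, member groups share one smooth
bin-profile template per (gene, mark); everything else is iid
Poisson(`background_rate = 1`) background. Templates are random walks
(Gaussian steps, sd `template_sd = 1`) shifted so their minimum is 0 —
non-negative, promoter-like, and with almost-surely nonzero variance,
so Pearson is always defined (truncating at 0 instead would zero out
whole-negative walks and create undefined correlations by accident).
Member groups receive `template + N(0, noise_sd)` per bin, clipped at 0;
with `noise_sd = 0` profiles are bitwise identical and within-block
correlations are exactly 1. Where blocks overlap, later blocks
overwrite earlier cells. Defaults state a 7-group, 6-histone-mark,
300-gene world with three planted blocks of 60/50/40 genes (20/17/13%
of genes, above the 10% support floor); `noise_sd = 0.25` is the
moderate-noise setting, a quarter of the template amplitude scale.

What a green recovery test establishes: the binning, coherence,
mining, intersection and maximality machinery recovers exactly the
planted structure. What it does not: robustness to read-level ChIP-seq
artifacts (fragment size, GC bias, mappability), replicate variation,
or group-specific depth pathologies — none are modelled.

Recovery is scored per truth block by best gene-set Jaccard, assigned
greedily without replacement; precision is the fraction of found
clusters matching some truth block at Jaccard ≥ 0.5. Under background
noise, a false coherent pair at θ = 0.65 with 10 bins occurs for ~2% of
gene-pair slots, so false patterns essentially never reach a 10%
support floor; conversely maximality can report small extra
sub-clusters of a planted block when a handful of background genes are
coherent for a subset of its marks — these score as near-duplicates,
not errors.

## Numerical choices

- Pearson is computed as `Σxy / sqrt(Σx²·Σy²)` on centered vectors and
  clipped to [−1, 1]; bitwise-identical inputs give exactly 1.0. The
  vectorized all-gene path uses the same formula and matches the scalar
  one to < 1e-12 (tested against `numpy.corrcoef`).
- Tensor TSVs are written with `%.17g` and read with round-trip float
  parsing, so write/read is exact.
- FP-growth output is canonically sorted (itemset size, then label
  order), making mining deterministic and input-order invariant.
- The threshold-sweep curve (`sweep_thresholds`) counts
  clique-consistent frequent patterns *before* maximality pruning.
  Transactions are antitone in θ, so this count is provably
  non-increasing; the *maximal* bicluster count is not — when a
  dominating cluster falls below support at higher θ, the sub-patterns
  it shadowed reappear, and the maximal count can tick upward. Reported
  biclusters keep the maximality rule; only the sweep uses the
  monotone quantity.

## Known limitations

- Whole-search-space intersection is exponential in the worst case; the
  candidate cap fails loudly instead of truncating, but very permissive
  θ / support settings on large rosters may hit it.
- `library_total` from the full track assumes tracks cover comparable
  genome fractions; the promoter-restricted variant is a flag
  (`library_from_promoters`) for inputs that do not.
- Only bedGraph/BED plain-text inputs are supported (no bigWig/BAM);
  no peak calling, background subtraction, replicate merging, or
  enrichment analysis downstream of the clusters.
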