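# Methods

## Scope and data model

The pipeline starts from *assembled, aligned* chloroplast genomes: an
aligned FASTA (one record per accession), a metadata TSV (accession id,
population group, subspecies type), and a GFF3-like feature map (gene,
feature class, strand, 1-based inclusive exon intervals, phase) against a
reference genome. Read mapping, consensus assembly and the multiple
alignment itself are out of scope; the synthetic generator emits gap-free
alignments (planted deletion alleles aside), so its columns correspond to
reference coordinates by construction. Coordinates are 1-based inclusive
throughout, matching the convention of organelle variant tables.

## Variant-effect prediction

Effects of single-position allele changes are predicted by direct codon
translation under the standard genetic code (translation tables 1 and 11
coincide for every codon involved here), not by an external impact
predictor: for a point substitution the codon is fully determined by the
feature map, so nothing more is needed. For minus-strand CDS the exonic
sequence is reverse-complemented before framing and codons are reported in
coding orientation — necessary, e.g., for a genomic A→G polymorphism to
surface as the coding-strand serine→proline change it actually is.
Overlapping annotations resolve deterministically by class priority
CDS > tRNA > rRNA > intron > intergenic, favouring protein-level calls.
Any gap allele yields an `indel` verdict with no codon analysis.
Stop-gain/stop-loss would be reported as nonsynonymous with a `*` symbol.
Positions not covered by any feature are intergenic; a reference allele
that contradicts the reference sequence is an error naming the position.

## Site classification

Alignment columns are tallied separately for the two domesticated clades.
N and ambiguity codes are dropped as missing; the gap character is kept as
a real fifth allele state (single-position deletions are legitimate
diagnostic sites). The category is a pure function of the two tally maps:

- fewer than two usable calls in either clade → `uninformative`;
- both clades monomorphic: same allele → `invariant`, different →
  `fixed_difference`;
- exactly one clade polymorphic → `mixed`;
- both polymorphic → `very_mixed`.

Monomorphism is strict (100 %), with no frequency tolerance: the target
statistic is "all members of one clade differ from all members of the
other". Multi-column indels are reported per column, not merged into
events. The headline count `n_functional_fixed` is the number of
fixed-difference records whose predicted effect is nonsynonymous or a
tRNA change. The polymorphism table prints alleles clade-B-first ("B/A"),
with the reference carrying the clade-B state.

## Distances and trees

TN93 distances use pairwise deletion (per pair, only the columns unusable
in that pair are dropped) and per-pair pooled base frequencies. Pairwise
deletion preserves signal on large alignments with scattered indels;
complete deletion would discard a column for every accession because one
accession is gapped there. Saturation (any log argument ≤ 0) is an error
naming the offending pair rather than a capped value — silently capped
distances distort neighbor joining. The all-pairs matrix is computed by
one-hot matrix products (exact for these integer counts) and is verified
in the tests to agree with the scalar pair function.

Neighbor joining evaluates the Q criterion on the upper triangle only
(floating-point broadcasting is not bit-symmetric and the join pair is
unordered) and breaks ties by the lexicographically smallest
(min, max) pair of subtree labels, where a subtree's label is the smallest
accession id it contains; repeated runs therefore produce byte-identical
Newick strings. Negative branch lengths are kept (and counted in a log
warning) because clamping breaks the exact-additivity property the test
oracles rely on; a `clamp_negative` flag is available. Rooting places the
root at the midpoint of the branch separating the outgroup leaf set from
everything else and errors if that set is not monophyletic.

Clade assignment finds the smallest clade containing every domesticated
accession (African accessions are tolerated inside it, reflecting their
placement within clade A, but keep the label `other`), errors with the
intruding leaves if any other group is inside, and splits it at its root
into its two children. The child with the larger indica proportion is
labelled A; an anchor accession can override this rule. Assignment is
invariant to leaf input order.

## The synthetic population generator

The generator emulates the *structure* the analysis assumes — two
long-diverged domesticated clades sister to wild Asian accessions, then
Australian, then the outgroup, with African accessions inside clade A and
South American accessions outside the Asian clade — not any particular
evolutionary model. Background divergence is per-site independent
substitution with transition:transversion weighting 2:1, applied along the
fixed lineage topology with named per-branch rates (expected
substitutions/site):

| branch | default |
|---|---|
| outgroup | 0.020 |
| south_american | 0.015 |
| australian | 0.008 |
| wild_asian | 0.004 |
| stem branches (australian/asian/domesticated) | 0.002 |
| clade_A, clade_B | 0.0025 each (A–B divergence 0.005) |
| african (from the clade-A consensus) | 0.0005 |
| private per-accession rate | 1e-4 |

These defaults put between-clade divergence 50× above within-clade
diversity, comfortably inside the regime where distance methods recover
the planted structure; all are overridable in the config, and a
`zero_background` switch leaves the planted sites as the only variable
columns.

Planted diagnostic sites are exact, not stochastic: after background
evolution the clade consensuses are overwritten with the configured
alleles, then for each site a seeded without-replacement sample of
accessions inside a clade is flipped to the opposite clade's allele. The
packaged configuration encodes the published diagnostic table: every
printed position with its B/A alleles and feature class, clade sizes
1486/1532, the psbB site's 88 within-clade-A carriers of the clade-B
allele, wild-group sizes 31/33/5/3/1, and the published per-clade
subspecies composition. Mixed and very-mixed rows without printed tallies
get a minority fraction of 0.1 of the polymorphic clade (clade A at mixed
rows, both clades at very-mixed rows) — a single fixed choice, large
enough to be unambiguous polymorphism and small enough to leave the
majority allele clear. Multi-base printed rows are expanded to one planted
site per column (53 columns in total).

Subspecies labels are assigned by exact largest-remainder quota on the
configured proportions with a seeded shuffle, so configured compositions
are reproduced exactly at any clade size; the published cross-tab's
unassigned remainders (1 accession in clade A, 19 in clade B) carry the
label `none`. The metadata additionally records each accession's
generating clade as ground truth for recovery tests.

The reference genome is a uniform-random ACGT draw in which every planted
position carries the clade-B (reference-side) allele, designed codons are
installed around planted CDS sites (so the printed amino-acid changes are
reproduced exactly, e.g. TGG→TTG for the tryptophan→leucine site and a
minus-strand TCT→CCT for serine→proline), and every other CDS codon is
redrawn until stop-free. The synthetic feature map places one exon per
planted CDS site, each a multiple of 3 long with the site at its designed
codon offset, so multi-site genes need no joint frame solving; synonymous
diagnostic sites sit at the third position of a four-fold degenerate
alanine codon. At genome lengths other than the real 135 kb span, planted
positions are remapped order-preservingly with a minimum spacing of 40 bp.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: alignment error and large structural variation
(inverted repeats, length polymorphism), rate heterogeneity across sites,
any realistic substitution process beyond the 2:1 transition bias,
recombination (none; appropriate for chloroplasts), and sequencing or
consensus-calling error. Tests demonstrate that the *analysis* recovers
planted structure exactly, not that real rice data contain that structure.

## Problem sizes and numerical choices

Scaled runs divide group sizes by a factor with half-up rounding, clamping
non-empty groups to at least one member so the outgroup (size 1) survives
scaling and rooting stays possible. The packaged test and demonstration
sizes are a 5 kb genome with either full clade sizes (planted-recovery
runs; the scan is linear in accessions × columns) or factor-10/50/100
populations for tree building (the distance matrix is quadratic in
accessions). Percent formatting uses decimal half-up rounding at the
displayed precision: composition percentages print 1 decimal at ≥ 10 %
and 2 decimals below; cross-tab percentages print 1 decimal with the
number of domesticated accessions as denominator (the published
cross-tab's own row totals are internally inconsistent with its percent
column; the configured domesticated total is used). Clade-share
percentages round to whole percent.

## Known limitations

- The scan classifies columns relative to exactly two clades; deeper
  partitions require repeated runs.
- TN93 assumes stationary base composition; strongly saturated pairs are
  refused rather than estimated.
- The NJ implementation is quadratic per join (cubic overall) — ample for
  thousands of accessions, but not for hundreds of thousands.
- Effect prediction handles point substitutions; multi-base substitutions
  are treated per column and frameshift consequences of indels are not
  modelled.
- A CDS position inside a partial leading codon (phase > 0) is an error
  rather than a call.
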