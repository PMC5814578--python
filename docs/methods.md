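# Methods

This note documents the statistical models, numerical conventions and
open design choices behind poolscan, and what validation on synthetic
data does and does not establish.

## Input model

All statistics are defined on a complete, biallelic, homozygous SNV
panel: after ingestion every retained site has exactly one allele code
(0 = ref, 1 = alt) per accession. Site filters follow the usual
RNA-seq-derived-call conventions: mapping quality ≥ 25 and read depth
> 2 (i.e. ≥ 3). The depth rule is applied per sample with a called
genotype by default because every downstream statistic needs complete
genotypes; a pooled-depth mode exists (`depth_mode="pooled"`) since
"coverage" is ambiguous between the two readings. Multiallelic sites
are dropped rather than decomposed — the similarity and F<sub>ST</sub>
statistics below are defined for biallelic sites only. Coordinates are
converted once, on ingestion, from VCF 1-based to 0-based half-open;
every writer converts back per format convention. The drop report is
conservative by construction: retained + Σ per-reason drops equals the
input record count, and this identity is asserted in tests.

## Pooled-group window similarity

Each group g of n<sub>g</sub> accessions is collapsed into a gene pool,
the per-site alt-allele frequency p̂<sub>g</sub> (no missing data, so
the haploid sample count is always n<sub>g</sub>). The per-site
similarity between two pools is

    s = 1 − |p̂₁ − p̂₂|        (method "freq", default)

chosen as the simplest symmetric statistic on pooled frequencies that
is bounded in [0, 1] and reduces to consensus-allele identity when both
pools are fixed. The exact per-site form used by the lineage of tools
this scan descends from is not published; a second candidate — the
fraction of sites whose pool-majority alleles agree, with half credit
when a pool sits at exactly 0.5 — is implemented behind
`method="major"`. Window similarity is the unweighted mean of s over
the SNVs in the window (undefined, reported NaN, for empty windows).

Windows are 500 kb sliding by 250 kb; the final window on each
chromosome is truncated at the chromosome end and windowing stops once
the end is reached (no redundant tail windows). A window qualifies when
it holds ≥ 25 SNVs and its best similarity to the focal pool is
≥ 0.95; it is then assigned to exactly the arg-max non-focal group.
Exact arg-max ties are excluded from assignment and counted separately,
preserving uniqueness and the exact partition

    qualifying = assigned + ties.

Similarity percentages sum *nominal* window lengths (end − start)
without merging the 250-kb overlaps: this keeps the partition identity
exact and the per-chromosome percentages summing to 100. Per-chromosome
percentages are normalised by the chromosome's total assigned length
(not its physical length); chromosomes without assignments are omitted
rather than reported as 0/0. The focal group is a parameter — scans
focused on the cultivated group and on the *qingke*-like group are both
meaningful.

## Windowed Weir–Cockerham F<sub>ST</sub>

Per-site differentiation between two groups uses the Weir & Cockerham
(1984) two-population variance components a (among populations), b
(among individuals within populations) and c (within individuals), with
the observed heterozygosity taken from the genotypes. On this panel the
panel is fully homozygous, so h̄ ≡ 0 and c ≡ 0 — exactly the
full-inbreeding case the observed-heterozygosity terms are designed to
absorb. Sample sizes enter as accession counts (the diploid convention
of standard VCF tools). One can show that for accessions contributing a
single effective allele each, E[a] = F·p(1−p) and E[a+b] = p(1−p) under
the Balding–Nichols model, so the ratio-of-sums estimator is unbiased
for the divergence parameter F; simulation at F = 0.2 (groups of 18 and
9, 20,000 sites) recovers 0.194–0.205 across seeds. A `ploidy=1` mode
is exposed for sensitivity analysis; on a homozygous panel it coincides
numerically with the diploid convention (all heterozygosity terms
vanish and the effective-allele count equals the accession count).

Window values are weighted: Σa / Σ(a+b+c) over the window's sites — not
the mean of per-site ratios, which is biased by low-information sites
(a test asserts the two diverge on a crafted case). Negative site and
window estimates are reported as computed (the estimator is centred
near 0 for undifferentiated groups) and participate in the threshold
quantile, mirroring common practice. Windows with a zero denominator
sum are undefined and excluded from the empirical threshold; the
threshold is the linear-interpolation (1 − top_frac) quantile of the
defined window values, with a fixed cut (e.g. 0.65) available instead.
Threshold-passing windows merge when overlapping or book-ended; sweep
fractions divide merged length by chromosome length. A gene counts as
swept on any ≥ 1 bp overlap with a merged region, once.

## Phylogeny

Distances are haploid p-distances (fraction of panel sites with
differing codes); the panel's homozygous coding makes this the natural
choice, and a Jukes–Cantor correction is available by flag. Trees are
built by the Saitou–Nei neighbour-joining agglomeration with standard
branch-length formulas; for additive inputs the topology and path
lengths are recovered exactly (verified to 1e-9 on random additive
matrices against an independent NJ implementation).

Exact ties on the Q-criterion deserve a note: with binary calls,
p-distances are rationals k/m and ties occur routinely. An index-order
tie rule would make the output depend on the order samples are listed,
which contradicts the requirement that bootstrap supports be invariant
to sample permutation. Ties are therefore broken by the
lexicographically smallest pair of clade labels (a clade's label being
the smallest leaf name it contains): deterministic *and*
order-invariant. Negative branch lengths are kept internally and
optionally clamped to zero on export, as GUI tree tools do.

Bootstrap supports resample site columns with replacement (the standard
for sequence data), rebuild the tree, and count recoveries of each
internal split of the original tree; supports are serialised as integer
internal-node labels (0–100). The random stream draws only column
indices, so for a fixed seed the supports do not depend on sample
order. Splits are encoded as the side not containing the smallest leaf
name, making the counting invariant to rooting at the trifurcation.

## Genome tracks

CpG islands: a window (default 10 kb, matching large-genome practice;
the classical definition uses much shorter windows) slides by 1 bp; a
placement passes when GC ≥ 0.5 and observed/expected CpG =
(#CG·L)/(#C·#G) ≥ 0.6. A position is marked when *every* placement
covering it passes, marked runs ≥ 200 bp are reported with
region-level mean GC and obs/exp. This position-coverage variant is
parameter-compatible with the well-known island plotters but not
guaranteed to reproduce any specific tool's smoothing, whose details
vary across versions; the divergence risk is confined to island
boundaries (the coverage rule erodes up to one window length at each
flank, which is why recovery tests bound the boundary error by half the
scan window). Scanning is case-insensitive; N bases count as non-C/G.

Densities are counts in nonoverlapping 500-kb windows; intervals are
assigned to the window containing their start so each feature is
counted exactly once and Σ window counts equals the feature total
(asserted). Low-diversity regions are maximal runs of windows whose SNV
count is *strictly* below a quantile (default 10%) of the track's
window counts, kept when the run spans ≥ `min_span` bp (default
100 Mb, the scale of interest for large cereal genomes; scale it down
with the data). With all windows equal nothing is strictly below the
quantile, so a flat track yields no regions. No printed threshold
exists for "very low diversity" in the motivating analyses, so the
quantile is a documented default, not a claim of equivalence.

## Synthetic data

The generator produces the study design directly rather than running a
coalescent: group allele frequencies follow Balding–Nichols — ancestral
p ~ Uniform(0.05, 0.95), group frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
— because this parameterises exactly the quantity the sweep scan
estimates (F) and runs in milliseconds. Defaults are the study scale:
2 × 50-Mb chromosomes, 25,000 SNVs each, groups 9/18/6/6, F = 0.15
(cultivated groups), 0.2 and 0.3 (wild groups), seed 42.

Two kinds of truth are planted. **Shared-ancestry blocks** (six of
2 Mb; donors QK and Wb-T) give the focal group and the donor one common
frequency per site, drawn with a high block-level fixation parameter
(`shared_fixation` = 0.98, a U-shaped beta concentrated at 0/1). The
near-fixation matters: identical-by-descent tracts in inbred crop
groups are near-fixed haplotypes, and only near-fixed shared
frequencies push window similarity above 0.95 once binomial sampling
noise from 9- and 18-accession pools is added (copying spread-out
frequencies would cap expected similarity near 0.86 and make the
criterion unreachable by any method — measured site similarity is
≈ 0.997 inside blocks vs ≈ 0.78 background). **Sweep blocks** (four of
1 Mb, QK vs MCB) redraw the two named groups from a high-divergence
beta (`sweep_divergence` = 0.8) until |Δp| ≥ 0.8, by rejection with
1000 bounded retries per site (an unsatisfiable floor raises an error);
a floor ≥ 0.999 plants exact fixed differences, since |Δp| = 1 has
probability zero under any continuous draw.

Genotypes draw one allele per accession per site
(Bernoulli(p<sub>g</sub>)), written as homozygous diploid VCF calls
with MQ and DP fields that pass the default filters, so the emitted VCF
round-trips through ingestion with zero drops. Gene annotations are
uniform non-overlapping intervals; sequences are AT-rich backgrounds
(GC ≈ 0.35 — above-threshold obs/exp but below-threshold GC, hence no
spurious islands) with planted CG-rich segments (GC ≈ 0.8, 12 kb so
they survive the 10-kb scan window). Sequences use a per-chromosome
panel length (default 300 kb) separate from the genotype coordinate
system — island detection needs sequence composition, not genome scale.
Everything is deterministic under the config seed; frequency, genotype
and annotation streams use offset seeds so stages can be re-run
independently.

What passing on this generator does **not** show: real panels have
linkage disequilibrium, recombination-graded block edges, missing data
and genotyping error, ascertainment bias in SNV discovery, and
unequal per-site information — none of which are modelled. Recovery
rates here validate the *implementation* (and the statistics'
behaviour under their own assumptions), not expected performance on
real data.

## Problem sizes used in validation

The default demo design (50,000 sites, 39 accessions, ~400 windows) is
the package's chosen validation scale: large enough that window
statistics concentrate (≥ ~250 SNVs per 500-kb window) and every
planted block spans several windows, small enough to iterate on
freely. F<sub>ST</sub> calibration uses 20,000 sites; NJ exactness 100
random 6–10-taxon trees; bootstrap determinism small replicate counts —
behaviour is replicate-count-independent by construction.

## Known limitations

- The similarity statistic is a design choice; published analyses in
  this family do not print their per-site formula, so absolute
  similarity values are comparable within poolscan runs, not across
  tools.
- The CpG scan's island boundaries are systematically conservative (see
  above) relative to mean-smoothing implementations.
- `empirical_threshold` computes the quantile after excluding undefined
  windows; computing it before exclusion is possible by passing the raw
  value array, and the two orders differ when many windows are empty.
- No LD or recombination modelling in the generator; sweep blocks have
  hard edges.
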