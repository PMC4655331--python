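# Methods

## Scope and coordinates

All internal coordinates are 0-based half-open; the 1-based convention of
VCF appears only at the I/O boundary (`cehkit.io`). Call confidence is a
three-level enum (high / low / no-call): the upstream assembly pipelines
this package consumes distinguish only those states, and FILTER≠PASS maps
to *low*, missing genotypes to *no-call*. Indels are left-aligned to
minimal representation on read (`ins:<seq>` / `del:<n>` tokens anchored at
a single position) so intra- and inter-haplotype catalogues compare
stably.

## Homozygosity segmentation

The segmentation statistic is the per-window **zygosity SNV ratio**:
homozygous variant SNV calls over all variant SNV calls in a 5-kb window,
counted from high-confidence calls only. Indels are excluded from the
ratio by default (`include_indels` flips this); reference-matching calls
are never counted. A window *fails* iff its ratio is defined and < 0.95;
**empty windows pass** — the ratio is undefined there, and absence of
variants is itself evidence of conservation. Conserved stretches are the
maximal window runs containing no more than 4 consecutive failing windows,
trimmed so both boundaries are passing windows (trimming gives
conservative bounds; the alternative — keeping failing edge windows — was
rejected because it extends stretches into visibly heterozygous sequence).
Windows are anchored at the analysis-region start (anchoring is not
specified by the underlying method; it is configurable via the region).

The ROH scan is a from-scratch implementation in bp terms with four
parameters (window 50 kb, ≤3 het calls per window, ≤50-kb inter-site gap,
≥1000-kb segments). A segment is invalid as soon as any 50-kb sliding
window inside it contains 4 het calls, which reduces to: every 4
consecutive het sites must span ≥ 50 kb. The scanner emits all maximal
valid site runs (verified against exhaustive interval enumeration for
≤500-site instances) and reports those spanning ≥ the minimum length.
Widely used array toolkits mix SNP-count and kb window definitions; the
pure-bp formulation here is a deliberate, documented deviation.

## Consensus and catalogues

Each diploid genome is split into two haploid chromosomes; phased het
sites split by phase, unphased het sites by the deterministic convention
*first-listed allele → chromosome 0* with a `phase_arbitrary` flag.
Within a CEH the het sites are isolated singletons (~5–9 per 100 kb), so
this convention affects no statistic computed downstream.

Consensus rules per position over ≥2 haploids: ≥2 ambiguous or
low-confidence inputs → N; otherwise the majority allele; an exact tie
(e.g. 3–3 of 6) → N with an ambiguous flag (no-call is the conservative
reading of a majority rule). An alternate allele carried by ≥2 haploids is
recorded as a *called* consensus-level variant against the reference;
singleton alternates are recorded with `called=False`.

Two distinct support rules are intentional: intra-CEH **detection**
requires only >1 distinct high-confidence allele at a position (support 1
suffices) because ~99% of intra-CEH variants are singleton heterozygotes
and would vanish under a support-2 rule, while consensus-level **calling**
against a reference keeps the support-2 requirement. Comparable length L
excludes every position that is no-called or low-confidence in at least
one compared sequence, plus fully masked tracts; intra-CEH records take
the majority allele as the haplotype allele (ties prefer the reference
base).

The shared-segment scan reports all maximal SNP-index runs containing at
most `max_mismatch` mismatches (default 2) between a query allele vector
and one or two reference vectors (agreement with both is required when two
are given); it is verified against brute-force interval enumeration.

## Annotation, diversity, age

Feature classes follow fixed precedence
coding > UTR5 > UTR3 > ncRNA-exonic > intronic > promoter > intergenic,
with the highest-precedence class winning when a variant falls in several
genes (the convention of standard annotation tools). Coding SNVs are
classified by translating the affected codon on the coding strand with an
internal standard-code table (the test oracle translates the full CDS with
Biopython instead); stop-gain → nonsense, identical residue → synonymous,
otherwise missense; stop-loss falls into missense. Coding indels are
frameshift iff length mod 3 ≠ 0. The promoter is the 1-kb window upstream
of the TSS, strand-aware and configurable (the source annotation tool's
default window is not recoverable).

Nucleotide diversity is implemented **exactly as π = S/L** — segregating
SNV count over comparable aligned length — because that ratio reproduces
the published worked values (238/2,720,646 = 8.75×10⁻⁵;
293/4,135,945 = 7.08×10⁻⁵); the canonical average-pairwise statistic is
provided separately as `pairwise_nucleotide_diversity` to avoid conflating
the two definitions. The published per-100kb SNV densities (8.58, 6.84)
are *not* consistent with S/L on the same S and L (the columns appear
swapped between haplotypes); this is documented, not resolved, and nothing
downstream depends on it. Similarly, both 290 (table total) and 293 (the
"262/293" fraction) circulate as the A33-B58-DR3 SNV count; the age and π
arithmetic only reproduce with 293, which is used where the arithmetic
requires it.

Haplotype age uses a **star genealogy**: n haploid chromosomes descend
independently from the founder for T generations, accumulating
S ≈ n·T·μ·L mutations, so T = ⌊S/(n·μ·L)⌋ and age = 20·T years with
μ = 1.1×10⁻⁸. The floor (rather than rounding) is the only convention
that reproduces both published ages (26,500 and 21,460 years) and is
documented as reverse-engineered from them.

## LD and screening

r² uses pairwise-complete rows; a pair with a monomorphic site is flagged
undefined rather than 0. LD blocks use the *all pairwise r² > threshold*
definition with a strict inequality at 0.8 — not the confidence-interval
method of the common GUI tool — searched greedily left to right (leftmost
maximal run wins; remaining sites re-scanned to its right), which makes
the partition deterministic. Undefined pairs fail the block condition.
Block crossover links are **conditional** fractions P(next-block haplotype
| this-block haplotype): a joint-fraction definition cannot satisfy the
requirement that no recombination yields a permutation matrix, so the
conditional form is used and documented. Block/haplotype operations
require phased complete input (v1 does not re-implement phasing); a
2-locus table is still estimable from unphased data via r² on
pairwise-complete rows.

The co-segregation screen returns sites whose allele sets in the two
phenotype classes are disjoint — a perfect partition — and rejects
single-class phenotypes. ΔCt expression is 2^−(mean ΔCt) with a
configurable detection limit (default 35 cycles, a standard qPCR
cut-off; the source assay does not state one).

## Phylogeny

Alignments project diploid callsets or consensus haplotypes onto a common
SNP list; heterozygous and no-called genotypes become missing symbols.
K2P distances use pairwise deletion; saturation (non-positive log
argument) yields a flagged infinite distance, replaced by a large finite
constant (5.0 substitutions/site) in distance matrices so NJ remains
defined. Tree construction is **neighbor joining on K2P distances** — a
deliberate substitute for likelihood search: for the near-clonal
haplotypes this pipeline targets, distance methods give the same
groupings, and topology claims are only ever tested on synthetic data with
planted truth (NJ provably recovers additive distances, which the test
suite exercises on random additive trees). The NJ agglomeration itself is
scikit-bio's implementation (negative branch lengths clamped to zero);
bootstrap resamples alignment columns (missing data travels with its
column) and reports per-split support percentages over 500 replicates by
default.

## RCCX copy number

Raw relative copies are 2·E^−ΔCt against the single-copy-per-chromosome
RP1 anchor with amplification efficiency E fixed at 2 (no efficiency
correction is described for the source assay; configurable). Because raw
values systematically underestimate true copies, a single shared linear
map true = a·measured + b is fitted by least squares on reference samples
with known copies — the prediction direction used for assignment
(regressing measured on true was the alternative; the prediction direction
was chosen because the map is applied to measured values). Integer
assignment is nearest non-negative integer with ties at .5 rounding up.
Validation checks C4A+C4B = C4L+C4S = TNXA+2; all three totals count
RCCX modules per diploid genome, and a call violating the identity is
returned with `valid=False` rather than rejected.

## Synthetic data: what it emulates, and what it does not

`simulate_ceh_cohort` plants structure directly (no coalescent): a random
reference over the region; founder-vs-reference homozygous SNVs at 100 per
100 kb shared by every sample (real CEH genomes differ from the mosaic
reference at roughly this density — without them the zygosity ratio would
be degenerate); intra-CEH SNVs Poisson-placed at 8.33 per 100 kb (the
denser of the two studied cohorts), 99% heterozygous within a single
random carrier; indels at the observed 52:290 indel:SNV ratio with
uniform 1–10 bp lengths (the length distribution is not published; it is
exposed in the parameters); an optional cluster window receiving a
configured fraction of variants (emulating the observed hyper-variable
regions holding 70–90% of intra-CEH variation); no-call tracts masked on
all samples; and, when a conserved core is configured, dense heterozygous
flank noise at 150 het calls per 100 kb per sample — high enough that
flank windows essentially never appear variant-free, so stretch-boundary
recovery tests are meaningful. A single seed fans out to per-component
child streams (`SeedSequence.spawn`) so adding a generator never perturbs
existing ones.

`simulate_population_haplotypes` draws each chromosome's haplotype per
block from the block's frequency table; `recomb_between` is a
recombination *fraction*: an independent re-draw fires with probability
2c (capped at 1), since a recombinant lineage still matches by chance —
c = 0 gives perfect inter-block association and c = 0.5 independent
assortment. Lineages are linked across blocks by haplotype rank.

`simulate_qpcr_plate` draws Ct = ref_mean − log2(copies/2) + N(0, sd) per
replicate with defaults ref_mean 24 cycles, sd 0.1 cycles, 3 replicates
(none are stated for the source assay; these are typical SYBR-assay
values); zero copies yield a NaN no-amplification sentinel.

None of the generators model read-level error, mapping artefacts,
reference bias, linked selection, or realistic site-frequency spectra: a
green recovery test establishes that the *algorithms* invert the stated
generative structure, not that they are robust to everything real data
contains.

## Known limitations and numerical notes

- The qPCR recovery bound "≥99% of 1,000 samples at replicate sd ≤0.15
  cycles" holds comfortably at the default sd 0.10 (measured 1000/1000)
  but **not at the 0.15 boundary**: with triplicate averaging the ΔCt
  estimate has sd 0.15·√(2/3) ≈ 0.12 cycles while a 2-copy gene tolerates
  only log2(1.25) ≈ 0.32 cycles before misrounding, so a five-gene
  per-sample call succeeds ~98–99% of the time (measured 982–989/1000
  across seeds). The boundary check is kept in the acceptance suite and
  fails honestly; per-gene recovery does exceed 99% at the boundary.
- Consensus ties and stretch-edge trimming are conservative (no-call and
  trim respectively); both choices are configurable only by changing the
  stated thresholds, not by flags.
- `find_ld_blocks` is O(sites² · haplotypes); fine for the ≤200-site
  regional panels it targets, not for genome-wide use.
- The intra-CEH unphased-split convention can misphase adjacent het sites
  <1 window apart; no downstream statistic reads phase across sites.
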