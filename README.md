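# cehkit

Toolkit for characterizing **conserved extended haplotypes (CEHs)** in the
human MHC region (chr6p21.3). CEHs are megabase-scale stretches of
near-identical sequence shared by unrelated carriers of the same HLA
haplotype; dissecting the sparse variation *inside* them — and the dense
variation *between* haplotypes — is the route to resolving disease
associations that blanket linkage disequilibrium otherwise confounds.

`cehkit` implements the full desk-side analysis around a small cohort of
MHC-homozygous genomes:

- **Homozygosity segmentation** — 5-kb window *zygosity SNV ratio*
  (homozygous variant calls over all variant calls per window); conserved
  stretches are maximal runs containing no more than 4 consecutive windows
  with ratio < 0.95. A from-scratch bp-scale **ROH scan** (50-kb sliding
  window, ≤3 het calls per window, ≤50-kb inter-site gaps, ≥1000-kb
  segments) covers SNP-array-density data.
- **Haploid consensus and variant catalogues** — n homozygous diploid
  genomes yield 2n haploid chromosomes; a position with ≥2
  ambiguous/low-confidence inputs is no-called, and an alternate allele is
  *called* against the reference when carried by ≥2 haploids. Intra-CEH
  *detection* records every position with >1 distinct high-confidence
  allele (most intra-CEH variants are singleton heterozygotes).
- **Annotation, diversity, age** — Table-style feature classes
  (missense/nonsense/synonymous by codon translation, frameshift indels,
  UTRs, ncRNA-exonic, intronic, promoter, intergenic); nucleotide diversity
  `π = S / L` (segregating SNVs over comparable length); star-genealogy
  haplotype age `T = ⌊S / (n·μ·L)⌋` generations with μ = 1.1×10⁻⁸ per site
  per generation, 20 y/generation, n = 6 haploid chromosomes.
- **LD and regulatory screening** — pairwise `r² = D²/(p_A q_A p_B q_B)`;
  LD blocks as maximal contiguous SNP runs with *all* pairwise r² > 0.8;
  block haplotype tables with crossover links; a co-segregation screen for
  variants that perfectly partition a binary expression phenotype; ΔCt
  relative expression (2^−ΔCt).
- **Phylogeny** — Kimura 2-parameter distances
  `d = −½·ln((1−2P−Q)·√(1−2Q))` with heterozygous calls as missing data,
  neighbor-joining trees, and column-bootstrap split support (n = 500).
- **RCCX copy number by qPCR** — relative copies `2·2^−ΔCt` against the
  single-copy RP1 anchor, linear calibration against reference lines with
  known copies, nearest-integer assignment, and the internal validation
  identity `C4A + C4B = C4L + C4S = TNXA + 2` (all three count total RCCX
  modules).
- **Synthetic cohorts with ground truth** — generators for CEH cohorts
  (founder haplotype, sparse mostly-heterozygous singleton SNVs, variant
  clusters, no-call tracts, conserved core with heterozygous flanks),
  phased population panels with planted LD blocks, and qPCR plates with
  replicate Ct noise; every downstream recovery test is driven by these.

## Worked example

```bash
cehkit demo --seed 1 --out demo_out
cat demo_out/diversity.json
```

```json
{
 "S": 83,
 "L": 1000000,
 "pi": 8.3e-05,
 "snv_per_100kb": 8.3,
 "het_fraction": 0.9894736842105263,
 "age_years": 25140.0
}
```

A 1-Mb synthetic cohort of three homozygous individuals carried 83
intra-CEH segregating SNVs over 10⁶ comparable bp, giving π = 8.3×10⁻⁵ —
the order of magnitude observed inside real CEHs and ~40-fold below typical
inter-haplotype MHC diversity. 99% of the variants are heterozygous within
their single carrier, and the star-genealogy estimate dates the simulated
founder to ≈25,140 years (1,257 generations). `demo_out/` also contains the
conserved-stretch BED, the intra-CEH catalogue TSV, recovered LD blocks,
and RCCX calls for a monomodular (C4A 2, C4B 0, TNXA 0) and a bimodular
(C4A 2, C4B 2, TNXA 2) genome, both passing the three-way module identity.

The same stages are available on real inputs: `cehkit stretches`, `roh`,
`consensus`, `catalog`, `diversity`, `age`, `ld`, `screen`, `phylo`,
`rccx`, and `simulate cohort|population|qpcr` (see `cehkit --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the library: the star-genealogy ages of
the two Asian CEHs from their published segregating-SNV counts and
comparable lengths (t3, t4), and the matching-SNP count of the maximal
shared segment in a freshly constructed 1508-SNP vector carrying exactly
two interior mismatches, scanned at mismatch tolerance 2 (t6). Results are
written as JSON to `--out`.
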