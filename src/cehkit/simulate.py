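"""Synthetic cohorts, haplotype panels, and qPCR plates with ground truth.

The generators plant structure directly (no coalescent machinery): a single
founder haplotype shared by a small cohort of MHC-homozygous individuals,
sparse mostly-heterozygous singleton SNVs, an optional hyper-variable
cluster, no-call tracts, an optional conserved core flanked by heterozygous
flanks; phased population panels with block-wise haplotype tables and
inter-block crossover; and qPCR plates with replicate Ct noise around true
integer copy numbers.

One global seed fans out to per-component child streams via
``numpy.random.SeedSequence.spawn`` so adding a generator never perturbs
existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    BASES,
    Confidence,
    DiploidCallset,
    GenomicRegion,
    NOCALL_ALLELE,
    ReferenceTrack,
    SiteCall,
)

NO_AMPLIFICATION = float("nan")


@dataclass
class CehSimParams:
    """Parameters of the conserved-extended-haplotype cohort generator.

    Defaults emulate the denser of the two studied Asian cohorts: three
    homozygous individuals over a ~3.1 Mb conserved region with ~8.3
    singleton SNVs per 100 kb, ~99% of them heterozygous within their
    carrier, and an indel:SNV ratio of 52:290.
    """

    region_length: int = 3_100_000
    chrom: str = "chr6"
    region_start: int = 29_000_000
    n_individuals: int = 3
    snv_rate: float = 8.33  # expected intra-CEH SNVs per 100 kb
    founder_snv_rate: float = 100.0  # founder-vs-reference hom SNVs per 100 kb
    het_fraction: float = 0.99
    indel_snv_ratio: float = 52.0 / 290.0
    indel_max_len: int = 10
    cluster: Optional[tuple[int, int, float]] = None  # (start, length, fraction)
    nocall_tracts: list[tuple[int, int]] = field(default_factory=list)
    core: Optional[tuple[int, int]] = None  # conserved core; flanks get het noise
    flank_het_rate: float = 150.0  # het variants per 100 kb outside the core
    genotyping_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snv_rate < 0 or self.flank_het_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must lie in [0, 1]")
        if self.cluster is not None:
            cs, cl, cf = self.cluster
            if not 0 <= cf <= 1:
                raise ValueError("cluster fraction must lie in [0, 1]")
            if cs < self.region_start or cs + cl > self.region_start + self.region_length:
                raise ValueError("cluster must lie inside the region")

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(
            self.chrom, self.region_start, self.region_start + self.region_length
        )


@dataclass
class PlantedVariant:
    pos: int
    ref: str
    alt: str
    carrier: str
    het: bool
    is_indel: bool = False


@dataclass
class SimTruth:
    """Ground truth emitted alongside every generator's output.

    ``variants`` holds the planted intra-CEH variants only;
    ``founder_variants`` are founder-vs-reference homozygous differences
    shared by every cohort member, and flank noise is in neither list.
    """

    variants: list[PlantedVariant] = field(default_factory=list)
    founder_variants: list[PlantedVariant] = field(default_factory=list)
    conserved_core: Optional[GenomicRegion] = None
    cluster: Optional[GenomicRegion] = None
    nocall_tracts: list[GenomicRegion] = field(default_factory=list)
    ld_block_bounds: list[tuple[int, int]] = field(default_factory=list)
    ld_block_freqs: list[dict[str, float]] = field(default_factory=list)
    true_copies: dict[str, dict[str, int]] = field(default_factory=dict)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, size=n)])


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[rng.integers(0, 3)]


def simulate_ceh_cohort(
    params: CehSimParams,
) -> tuple[list[DiploidCallset], ReferenceTrack, SimTruth]:
    """Simulate a cohort of individuals homozygous for one founder haplotype.

    SNVs are Poisson-placed at ``snv_rate`` per 100 kb; a configured cluster
    receives its fraction of variants uniformly within its window; each
    variant is carried by one individual, heterozygous with probability
    ``het_fraction`` (on one random chromosome) and homozygous otherwise.
    No-call tracts are masked on every sample. With ``core`` set, dense
    heterozygous variation is added outside the core so segmentation can be
    benchmarked against the planted bounds.
    """
    region = params.region
    rng_ref, rng_pos, rng_assign, rng_flank, rng_err = _child_rngs(params.seed, 5)
    ref_seq = _random_sequence(rng_ref, region.length)
    reference = ReferenceTrack(region=region, sequence=ref_seq)
    samples = [f"S{i + 1}" for i in range(params.n_individuals)]

    core = (
        GenomicRegion(params.chrom, *params.core) if params.core is not None else None
    )
    place_lo, place_hi = (core.start, core.end) if core else (region.start, region.end)
    place_len = place_hi - place_lo

    n_snv = rng_pos.poisson(params.snv_rate * place_len / 1e5)
    n_indel = rng_pos.poisson(params.snv_rate * params.indel_snv_ratio * place_len / 1e5)

    taken: set[int] = set()

    def draw_positions(n: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
        out: list[int] = []
        while len(out) < n:
            p = int(rng.integers(lo, hi))
            if p not in taken:
                taken.add(p)
                out.append(p)
        return out

    positions: list[int] = []
    if params.cluster is not None:
        cs, cl, cf = params.cluster
        n_in_cluster = int(rng_pos.binomial(n_snv, cf))
        positions += draw_positions(n_in_cluster, cs, cs + cl, rng_pos)
        positions += draw_positions(n_snv - n_in_cluster, place_lo, place_hi, rng_pos)
    else:
        positions += draw_positions(n_snv, place_lo, place_hi, rng_pos)
    indel_positions = draw_positions(n_indel, place_lo, place_hi, rng_pos)

    truth = SimTruth(
        conserved_core=core,
        cluster=GenomicRegion(params.chrom, params.cluster[0], params.cluster[0] + params.cluster[1])
        if params.cluster
        else None,
        nocall_tracts=[
            GenomicRegion(params.chrom, s, s + l) for s, l in params.nocall_tracts
        ],
    )
    for pos in sorted(positions):
        ref = reference.base(pos)
        truth.variants.append(
            PlantedVariant(
                pos=pos,
                ref=ref,
                alt=_alt_base(rng_assign, ref),
                carrier=samples[rng_assign.integers(0, len(samples))],
                het=bool(rng_assign.random() < params.het_fraction),
            )
        )
    for pos in sorted(indel_positions):
        ref = reference.base(pos)
        length = int(rng_assign.integers(1, params.indel_max_len + 1))
        if rng_assign.random() < 0.5:
            alt = "ins:" + _random_sequence(rng_assign, length)
        else:
            alt = f"del:{length}"
        truth.variants.append(
            PlantedVariant(
                pos=pos,
                ref=ref,
                alt=alt,
                carrier=samples[rng_assign.integers(0, len(samples))],
                het=bool(rng_assign.random() < params.het_fraction),
                is_indel=True,
            )
        )

    # founder-vs-reference homozygous differences shared by all samples
    n_founder = rng_pos.poisson(params.founder_snv_rate * region.length / 1e5)
    for pos in sorted(draw_positions(n_founder, region.start, region.end, rng_pos)):
        ref = reference.base(pos)
        truth.founder_variants.append(
            PlantedVariant(
                pos=pos, ref=ref, alt=_alt_base(rng_pos, ref), carrier="*", het=False
            )
        )

    # dense heterozygous noise outside the conserved core (all samples share
    # founder state only inside the core; flanks are individual-specific)
    flank_variants: list[PlantedVariant] = []
    if core is not None:
        for lo, hi in ((region.start, core.start), (core.end, region.end)):
            if hi <= lo:
                continue
            n_f = rng_flank.poisson(params.flank_het_rate * (hi - lo) / 1e5 * len(samples))
            for pos in draw_positions(n_f, lo, hi, rng_flank):
                ref = reference.base(pos)
                flank_variants.append(
                    PlantedVariant(
                        pos=pos,
                        ref=ref,
                        alt=_alt_base(rng_flank, ref),
                        carrier=samples[rng_flank.integers(0, len(samples))],
                        het=True,
                    )
                )

    all_planted = sorted(
        truth.variants + truth.founder_variants + flank_variants, key=lambda v: v.pos
    )
    nocalls = truth.nocall_tracts
    chrom_pick = {
        id(v): int(rng_assign.integers(0, 2)) for v in all_planted if v.het
    }

    callsets = []
    for sample in samples:
        calls: list[SiteCall] = []
        for v in all_planted:
            if any(t.contains(v.pos) for t in nocalls):
                calls.append(
                    SiteCall(
                        pos=v.pos,
                        ref=v.ref,
                        alleles=(NOCALL_ALLELE, NOCALL_ALLELE),
                        confidence=Confidence.NOCALL,
                    )
                )
                continue
            if v.carrier == "*":
                alleles = (v.alt, v.alt)
            elif v.carrier == sample:
                if v.het:
                    pair = [v.ref, v.ref]
                    pair[chrom_pick[id(v)]] = v.alt
                    alleles = tuple(pair)
                else:
                    alleles = (v.alt, v.alt)
            else:
                alleles = (v.ref, v.ref)
            if params.genotyping_error > 0 and not v.is_indel:
                alleles = tuple(
                    _alt_base(rng_err, a)
                    if rng_err.random() < params.genotyping_error
                    else a
                    for a in alleles
                )
            calls.append(
                SiteCall(pos=v.pos, ref=v.ref, alleles=alleles, phased=True)  # type: ignore[arg-type]
            )
        callsets.append(
            DiploidCallset(
                sample_id=sample, region=region, calls=calls, masked=list(nocalls)
            )
        )
    return callsets, reference, truth


def simulate_population_haplotypes(
    n_hap: int,
    blocks: Sequence[tuple[int, dict[str, float]]],
    recomb_between: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate a phased {0,1} haplotype panel with planted LD blocks.

    ``blocks`` is a list of ``(n_snps, {haplotype_string: frequency})``; each
    chromosome draws one haplotype per block from the block's table.
    ``recomb_between`` is the recombination fraction between adjacent
    blocks: a chromosome's lineage is re-drawn independently from the next
    block's table with probability ``2 * recomb_between`` (capped at 1), so
    0 yields perfect inter-block association and 0.5 free recombination
    (a recombinant lineage still matches by chance, which is why the fresh
    draw fires at twice the fraction). Without a re-draw the chromosome
    keeps its haplotype rank (re-drawn anyway when the next block's table
    is smaller).
    """
    if n_hap < 1:
        raise ValueError("need at least one haplotype")
    rng = _child_rngs(seed, 1)[0]
    tables = []
    for n_snps, freqs in blocks:
        if not freqs:
            raise ValueError("each block needs at least one haplotype")
        haps = sorted(freqs)
        p = np.array([freqs[h] for h in haps], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("block haplotype frequencies must sum to 1")
        for h in haps:
            if len(h) != n_snps or any(c not in "01" for c in h):
                raise ValueError(f"haplotype {h!r} does not match block width {n_snps}")
        tables.append((haps, p))

    total = sum(n for n, _ in blocks)
    matrix = np.zeros((n_hap, total), dtype=np.int8)
    bounds = []
    offset = 0
    choice = np.full(n_hap, -1, dtype=int)
    for bi, ((n_snps, _), (haps, p)) in enumerate(zip(blocks, tables)):
        fresh = rng.choice(len(haps), size=n_hap, p=p)
        if bi == 0:
            choice = fresh
        else:
            crossover = rng.random(n_hap) < min(1.0, 2.0 * recomb_between)
            keep = (~crossover) & (choice < len(haps))
            choice = np.where(keep, choice, fresh)
        for i in range(n_hap):
            matrix[i, offset : offset + n_snps] = [int(c) for c in haps[choice[i]]]
        bounds.append((offset, offset + n_snps))
        offset += n_snps
    truth = SimTruth(
        ld_block_bounds=bounds, ld_block_freqs=[dict(f) for _, f in blocks]
    )
    return matrix, truth


def simulate_qpcr_plate(
    true_copies: dict[str, dict[str, int]],
    ct_ref_mean: float = 24.0,
    sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    ref_gene: str = "RP1",
):
    """Simulate a qPCR plate around true integer copy numbers.

    Ct_target = ct_ref_mean - log2(copies / 2) + Normal(0, sd) per replicate
    (the reference gene is diploid, so two target copies give dCt = 0);
    zero copies yield the no-amplification sentinel (NaN). Returns a tidy
    DataFrame (sample, gene, replicate, ct) including reference-gene rows,
    plus the truth record.
    """
    import pandas as pd

    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = _child_rngs(seed, 1)[0]
    rows = []
    for sample, genes in true_copies.items():
        for rep in range(replicates):
            rows.append(
                (sample, ref_gene, rep, ct_ref_mean + rng.normal(0.0, sd))
            )
        for gene, copies in genes.items():
            if copies < 0:
                raise ValueError("copies must be >= 0")
            for rep in range(replicates):
                if copies == 0:
                    ct = NO_AMPLIFICATION
                else:
                    ct = ct_ref_mean - np.log2(copies / 2.0) + rng.normal(0.0, sd)
                rows.append((sample, gene, rep, ct))
    plate = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    truth = SimTruth(true_copies={s: dict(g) for s, g in true_copies.items()})
    return plate, truth
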