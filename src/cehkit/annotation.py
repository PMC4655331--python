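"""Feature-class annotation, windowed variation profiles, diversity, and age.

Variants are assigned exactly one feature class with fixed precedence
coding > UTR5 > UTR3 > ncRNA-exonic > intronic > promoter > intergenic;
coding SNVs are classified by translating the affected codon on the coding
strand, coding indels by frame preservation. The promoter is the 1-kb
window upstream of the TSS, strand-aware (configurable).

Nucleotide diversity here is defined as segregating SNV count over
comparable aligned length, pi = S / L — the ratio that reproduces the
published worked examples; the canonical average-pairwise statistic is
available separately as :func:`pairwise_nucleotide_diversity`.

Haplotype age uses a star genealogy: n haploid chromosomes descending
independently from the founder for T generations accumulate S ~ n*T*mu*L
mutations, so T = floor(S / (n*mu*L)) and age = T * generation_years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core import (
    GeneModel,
    GenomicRegion,
    ReferenceTrack,
    VariantRecord,
    VariantType,
    ZygosityForm,
)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FeatureClass(str, Enum):
    MISSENSE = "coding-missense"
    NONSENSE = "coding-nonsense"
    SYNONYMOUS = "coding-synonymous"
    FRAMESHIFT = "coding-frameshift"
    NON_FRAMESHIFT = "coding-non-frameshift"
    NCRNA_EXONIC = "ncRNA-exonic"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "intronic"
    PROMOTER = "promoter"
    INTERGENIC = "intergenic"


_PRECEDENCE = {
    FeatureClass.NONSENSE: 0,
    FeatureClass.MISSENSE: 0,
    FeatureClass.SYNONYMOUS: 0,
    FeatureClass.FRAMESHIFT: 0,
    FeatureClass.NON_FRAMESHIFT: 0,
    FeatureClass.UTR5: 1,
    FeatureClass.UTR3: 2,
    FeatureClass.NCRNA_EXONIC: 3,
    FeatureClass.INTRONIC: 4,
    FeatureClass.PROMOTER: 5,
    FeatureClass.INTERGENIC: 6,
}


def _promoter_region(model: GeneModel, promoter_bp: int) -> Optional[GenomicRegion]:
    if model.strand == "+":
        start = max(0, model.tx.start - promoter_bp)
        if model.tx.start > start:
            return GenomicRegion(model.tx.chrom, start, model.tx.start)
        return None
    return GenomicRegion(model.tx.chrom, model.tx.end, model.tx.end + promoter_bp)


def _coding_effect(
    v: VariantRecord, model: GeneModel, reference: ReferenceTrack
) -> FeatureClass:
    if v.vtype is VariantType.INSERTION:
        length = len(v.alt[4:])
        return FeatureClass.FRAMESHIFT if length % 3 else FeatureClass.NON_FRAMESHIFT
    if v.vtype is VariantType.DELETION:
        length = int(v.alt[4:])
        return FeatureClass.FRAMESHIFT if length % 3 else FeatureClass.NON_FRAMESHIFT
    # SNV: locate the codon on the coding strand
    segs = model.cds_segments
    ordered = segs if model.strand == "+" else list(reversed(segs))
    cds_offset = 0
    hit = None
    for seg, _frame in ordered:
        if seg.contains(v.pos):
            if model.strand == "+":
                hit = cds_offset + (v.pos - seg.start)
            else:
                hit = cds_offset + (seg.end - 1 - v.pos)
            break
        cds_offset += seg.length
    if hit is None:
        raise ValueError(f"variant at {v.pos} not inside CDS of {model.gene}")
    codon_index, within = divmod(hit, 3)
    # gather the three genomic positions of the codon in coding-strand order
    coding_positions: list[int] = []
    for seg, _frame in ordered:
        rng = (
            range(seg.start, seg.end)
            if model.strand == "+"
            else range(seg.end - 1, seg.start - 1, -1)
        )
        coding_positions.extend(rng)
    codon_pos = coding_positions[codon_index * 3 : codon_index * 3 + 3]

    def strand_base(pos: int, override: Optional[str] = None) -> str:
        b = override if override is not None else reference.base(pos)
        return b.translate(COMPLEMENT) if model.strand == "-" else b

    ref_codon = "".join(strand_base(p) for p in codon_pos)
    alt_codon = "".join(
        strand_base(p, v.alt if i == within else None)
        for i, p in enumerate(codon_pos)
    )
    ref_aa = CODON_TABLE.get(ref_codon, "X")
    alt_aa = CODON_TABLE.get(alt_codon, "X")
    if alt_aa == "*" and ref_aa != "*":
        return FeatureClass.NONSENSE
    if ref_aa == alt_aa:
        return FeatureClass.SYNONYMOUS
    return FeatureClass.MISSENSE


def annotate_variant(
    v: VariantRecord,
    models: Sequence[GeneModel],
    reference: Optional[ReferenceTrack] = None,
    promoter_bp: int = 1_000,
) -> FeatureClass:
    """Assign the single highest-precedence feature class to a variant."""
    candidates: list[FeatureClass] = []
    for model in models:
        if not model.is_ncRNA and any(
            seg.contains(v.pos) for seg, _ in model.cds_segments
        ):
            if reference is None:
                raise ValueError("coding annotation requires a reference track")
            candidates.append(_coding_effect(v, model, reference))
            continue
        if any(r.contains(v.pos) for r in model.utr5):
            candidates.append(FeatureClass.UTR5)
            continue
        if any(r.contains(v.pos) for r in model.utr3):
            candidates.append(FeatureClass.UTR3)
            continue
        if model.is_ncRNA and any(r.contains(v.pos) for r in model.exons):
            candidates.append(FeatureClass.NCRNA_EXONIC)
            continue
        if model.tx.contains(v.pos):
            candidates.append(FeatureClass.INTRONIC)
            continue
        prom = _promoter_region(model, promoter_bp)
        if prom is not None and prom.contains(v.pos):
            candidates.append(FeatureClass.PROMOTER)
    if not candidates:
        return FeatureClass.INTERGENIC
    return min(candidates, key=lambda c: _PRECEDENCE[c])


@dataclass
class BinnedVariation:
    windows: list[GenomicRegion]
    snv_counts: np.ndarray
    indel_counts: np.ndarray
    histogram: dict[int, int]
    decile_cumulative: list[float]
    top_decile_range: tuple[int, int]

    @property
    def total_counts(self) -> np.ndarray:
        return self.snv_counts + self.indel_counts


def bin_variation(
    catalog: Sequence[VariantRecord],
    region: GenomicRegion,
    window: int = 5_000,
) -> BinnedVariation:
    """Bin a variant catalogue into fixed windows.

    Produces per-window SNV/indel counts, the frequency histogram of window
    totals, the cumulative share of variants captured by each 10% quantile
    of windows (ranked by decreasing count), and the (min, max) count among
    the top-decile windows.
    """
    n_windows = math.ceil(region.length / window)
    windows = [
        GenomicRegion(
            region.chrom,
            region.start + i * window,
            min(region.start + (i + 1) * window, region.end),
        )
        for i in range(n_windows)
    ]
    snv = np.zeros(n_windows, dtype=int)
    indel = np.zeros(n_windows, dtype=int)
    for v in catalog:
        if not region.contains(v.pos):
            raise ValueError(f"variant at {v.pos} outside region {region}")
        i = (v.pos - region.start) // window
        if v.vtype is VariantType.SNV:
            snv[i] += 1
        else:
            indel[i] += 1
    totals = snv + indel
    histogram = {int(k): int(c) for k, c in zip(*np.unique(totals, return_counts=True))}
    order = np.sort(totals)[::-1]
    groups = np.array_split(order, 10)
    total_variants = totals.sum()
    cum, acc = [], 0
    for g in groups:
        acc += g.sum()
        cum.append(acc / total_variants if total_variants else 0.0)
    top = groups[0]
    top_range = (int(top.min()), int(top.max())) if len(top) else (0, 0)
    return BinnedVariation(
        windows=windows,
        snv_counts=snv,
        indel_counts=indel,
        histogram=histogram,
        decile_cumulative=cum,
        top_decile_range=top_range,
    )


def flag_variation_regions(
    catalog: Sequence[VariantRecord],
    region: GenomicRegion,
    window: int = 30_000,
    low_max: int = 3,
    high_min: int = 15,
) -> list[tuple[GenomicRegion, str]]:
    """Label 30-kb windows with strictly fewer than ``low_max`` variants LOW
    and strictly more than ``high_min`` HIGH; adjacent same-label windows
    are merged."""
    binned = bin_variation(catalog, region, window=window)
    labels = []
    for w, c in zip(binned.windows, binned.total_counts):
        if c < low_max:
            labels.append((w, "LOW"))
        elif c > high_min:
            labels.append((w, "HIGH"))
    merged: list[tuple[GenomicRegion, str]] = []
    for w, lab in labels:
        if merged and merged[-1][1] == lab and merged[-1][0].end == w.start:
            merged[-1] = (GenomicRegion(w.chrom, merged[-1][0].start, w.end), lab)
        else:
            merged.append((w, lab))
    return merged


@dataclass
class DiversityStats:
    S: int
    L: int
    pi: float
    snv_per_100kb: float
    indel_per_100kb: float
    het_fraction: float


def diversity_stats(
    S: int,
    L: int,
    catalog: Optional[Sequence[VariantRecord]] = None,
    n_indels: int = 0,
) -> DiversityStats:
    """Diversity summary with pi = S / L (segregating SNVs over comparable bp)."""
    if L <= 0:
        raise ValueError("comparable length L must be positive")
    if S < 0:
        raise ValueError("S must be >= 0")
    het_fraction = float("nan")
    if catalog:
        n_het = sum(
            1 for v in catalog if v.zygosity_form is ZygosityForm.HETEROZYGOUS
        )
        het_fraction = n_het / len(catalog)
    return DiversityStats(
        S=S,
        L=L,
        pi=S / L,
        snv_per_100kb=1e5 * S / L,
        indel_per_100kb=1e5 * n_indels / L,
        het_fraction=het_fraction,
    )


def pairwise_nucleotide_diversity(haplotypes: np.ndarray, L: int) -> float:
    """Canonical average pairwise difference per site over n haplotypes."""
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 2 or L <= 0:
        raise ValueError("need >= 2 haplotypes and positive L")
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int(np.sum(h[i] != h[j]))
    return diffs / (n * (n - 1) / 2) / L


@dataclass
class AgeModel:
    """Star-genealogy age model: S segregating mutations across n haploid
    chromosomes over T generations at rate mu per site per generation."""

    mu: float = 1.1e-8
    gen_years: float = 20.0
    n_chrom: int = 6

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gen_years <= 0 or self.n_chrom < 1:
            raise ValueError("invalid age-model parameters")


def estimate_age(S: int, L: int, model: AgeModel = AgeModel()) -> float:
    """Age in years: floor(S / (n_chrom * mu * L)) generations * gen_years."""
    if S < 0 or L <= 0:
        raise ValueError("require S >= 0 and L > 0")
    T_gen = math.floor(S / (model.n_chrom * model.mu * L))
    return model.gen_years * T_gen
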