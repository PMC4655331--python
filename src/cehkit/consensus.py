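"""Haploid splitting, consensus construction, and variant catalogues.

A cohort of n MHC-homozygous diploid genomes yields 2n haploid chromosomes.
The consensus rules: a position where two or more haploids are ambiguous or
low-confidence is no-called (N); otherwise the consensus is the majority
allele with exact ties no-called; an alternate allele is *called* as a
consensus-level variant against the reference when at least ``min_support``
haploids carry it. Intra-CEH *detection*, by contrast, records every
position where more than one distinct allele occurs among high-confidence
haploids — most intra-CEH variants are singleton heterozygotes and would
vanish under a support-2 rule.

Comparable length L excludes every position no-called or low-confidence in
at least one compared sequence, plus fully masked tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    Confidence,
    DiploidCallset,
    GenomicRegion,
    NOCALL_ALLELE,
    ReferenceTrack,
    VariantRecord,
    ZygosityForm,
    variant_type_of,
)


@dataclass
class HaploidSequence:
    """Per-position calls of one chromosome of one sample (sparse: only
    positions present in the source callset are represented)."""

    source_sample: str
    chrom_index: int
    region: GenomicRegion
    positions: np.ndarray
    alleles: list[str]
    confidence: list[Confidence]
    phase_arbitrary: np.ndarray  # True where the het split used the convention
    masked: list[GenomicRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ConsensusHaplotype:
    name: str
    region: GenomicRegion
    positions: np.ndarray
    calls: list[str]  # allele token or N
    support: np.ndarray  # haploids agreeing with the consensus call
    ambiguous_positions: list[int]
    variants: list[VariantRecord] = field(default_factory=list)
    masked: list[GenomicRegion] = field(default_factory=list)


def split_haploids(callset: DiploidCallset) -> tuple[HaploidSequence, HaploidSequence]:
    """Split a diploid callset into its two haploid chromosomes.

    Phased het sites split by phase; unphased het sites follow the
    deterministic convention first-listed-allele -> chromosome 0 and are
    flagged phase-arbitrary. Low-confidence sites propagate to both
    haploids; no-calls become N on both.
    """
    pos = np.array([c.pos for c in callset.calls], dtype=int)
    out = []
    for k in (0, 1):
        alleles, conf, arb = [], [], []
        for c in callset.calls:
            if c.confidence == Confidence.NOCALL:
                alleles.append(NOCALL_ALLELE)
            else:
                alleles.append(c.alleles[k])
            conf.append(c.confidence)
            arb.append(c.is_het and not c.phased)
        out.append(
            HaploidSequence(
                source_sample=callset.sample_id,
                chrom_index=k,
                region=callset.region,
                positions=pos,
                alleles=alleles,
                confidence=conf,
                phase_arbitrary=np.array(arb, dtype=bool),
                masked=list(callset.masked),
            )
        )
    return out[0], out[1]


def _check_same_span(haploids: Sequence[HaploidSequence]) -> np.ndarray:
    first = haploids[0].positions
    for h in haploids[1:]:
        if len(h.positions) != len(first) or not np.array_equal(h.positions, first):
            raise ValueError("haploids must cover identical position spans")
    return first


def _merge_intervals(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    merged = [regions[0]]
    for r in regions[1:]:
        last = merged[-1]
        if r.chrom == last.chrom and r.start <= last.end:
            if r.end > last.end:
                merged[-1] = GenomicRegion(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return merged


def build_consensus(
    haploids: Sequence[HaploidSequence],
    reference: Optional[ReferenceTrack] = None,
    min_support: int = 2,
    name: str = "consensus",
) -> ConsensusHaplotype:
    """Build the consensus haplotype of >= 2 haploid chromosomes.

    Per position: >= 2 ambiguous/low-confidence inputs -> N; otherwise the
    majority allele among high-confidence inputs, with exact ties no-called
    and flagged ambiguous. When a reference is supplied, alternate alleles
    carried by >= ``min_support`` haploids are recorded as called variants;
    lower-support alternates are recorded with ``called=False``.
    """
    if len(haploids) < 2:
        raise ValueError("need at least two haploids")
    positions = _check_same_span(haploids)
    calls: list[str] = []
    support = np.zeros(len(positions), dtype=int)
    ambiguous: list[int] = []
    variants: list[VariantRecord] = []
    for j, pos in enumerate(positions):
        states = [(h.alleles[j], h.confidence[j]) for h in haploids]
        n_bad = sum(
            1 for a, c in states if c != Confidence.HIGH or a == NOCALL_ALLELE
        )
        if n_bad >= 2:
            calls.append(NOCALL_ALLELE)
            continue
        good = [a for a, c in states if c == Confidence.HIGH and a != NOCALL_ALLELE]
        values, counts = np.unique(good, return_counts=True)
        order = np.argsort(counts)[::-1]
        if len(values) > 1 and counts[order[0]] == counts[order[1]]:
            calls.append(NOCALL_ALLELE)
            ambiguous.append(int(pos))
            continue
        top = str(values[order[0]])
        calls.append(top)
        support[j] = int(counts[order[0]])
        if reference is not None:
            ref = reference.base(int(pos))
            for v, c in zip(values, counts):
                v = str(v)
                if v != ref:
                    variants.append(
                        VariantRecord(
                            pos=int(pos),
                            ref=ref,
                            alt=v,
                            vtype=variant_type_of(ref, v),
                            support=int(c),
                            called=bool(c >= min_support),
                        )
                    )
    return ConsensusHaplotype(
        name=name,
        region=haploids[0].region,
        positions=positions,
        calls=calls,
        support=support,
        ambiguous_positions=ambiguous,
        variants=variants,
        masked=_merge_intervals([m for h in haploids for m in h.masked]),
    )


def intra_ceh_catalog(
    haploids: Sequence[HaploidSequence],
    samples: Sequence[DiploidCallset],
    reference: Optional[ReferenceTrack] = None,
) -> list[VariantRecord]:
    """Catalogue intra-CEH variation among haploid chromosomes of one CEH.

    A record is emitted at every position where all inputs are
    high-confidence and more than one distinct allele occurs. The majority
    allele is taken as the haplotype (CEH) allele; each minority allele
    yields one record whose zygosity form reflects the carrier's diploid
    genotype. Positions with any ambiguity are skipped (and excluded from
    comparable length, see :func:`comparable_length`).
    """
    positions = _check_same_span(haploids)
    sample_lookup = {cs.sample_id: {c.pos: c for c in cs.calls} for cs in samples}
    records: list[VariantRecord] = []
    for j, pos in enumerate(positions):
        states = [(h.alleles[j], h.confidence[j]) for h in haploids]
        if any(c != Confidence.HIGH or a == NOCALL_ALLELE for a, c in states):
            continue
        alleles = [a for a, _ in states]
        values, counts = np.unique(alleles, return_counts=True)
        if len(values) < 2:
            continue
        order = np.argsort(counts)[::-1]
        top = str(values[order[0]])
        if len(values) > 1 and counts[order[0]] == counts[order[1]]:
            # tie: prefer the reference base as the haplotype allele
            if reference is not None:
                ref_base = reference.base(int(pos))
                tied = {
                    str(values[o])
                    for o in order
                    if counts[o] == counts[order[0]]
                }
                if ref_base in tied:
                    top = ref_base
                else:
                    top = sorted(tied)[0]
            else:
                top = sorted(
                    str(values[o]) for o in order if counts[o] == counts[order[0]]
                )[0]
        for v, c in zip(values, counts):
            v = str(v)
            if v == top:
                continue
            form = None
            carriers = [
                cs
                for cs in samples
                if (call := sample_lookup[cs.sample_id].get(int(pos))) is not None
                and v in call.alleles
            ]
            if carriers:
                forms = {
                    ZygosityForm.HETEROZYGOUS
                    if sample_lookup[cs.sample_id][int(pos)].is_het
                    else ZygosityForm.HOMOZYGOUS
                    for cs in carriers
                }
                form = forms.pop() if len(forms) == 1 else ZygosityForm.MIXED
            records.append(
                VariantRecord(
                    pos=int(pos),
                    ref=top,
                    alt=v,
                    vtype=variant_type_of(top, v),
                    support=int(c),
                    zygosity_form=form,
                    called=bool(c >= 2),
                )
            )
    return records


def comparable_length(
    region: GenomicRegion,
    haploids: Sequence[HaploidSequence],
) -> int:
    """Region bp minus masked tracts and per-site ambiguous positions."""
    excluded = _merge_intervals(
        [m for h in haploids for m in h.masked]
    )
    excl_bp = sum(
        max(0, min(r.end, region.end) - max(r.start, region.start)) for r in excluded
    )
    positions = _check_same_span(haploids)
    site_excl = 0
    for j, pos in enumerate(positions):
        if any(t.contains(int(pos)) for t in excluded):
            continue  # already counted via the tract
        if any(
            h.confidence[j] != Confidence.HIGH or h.alleles[j] == NOCALL_ALLELE
            for h in haploids
        ):
            site_excl += 1
    return region.length - excl_bp - site_excl


def inter_haplotype_catalog(
    a: ConsensusHaplotype, b: ConsensusHaplotype
) -> tuple[list[VariantRecord], int]:
    """Differences between two consensus haplotypes on one coordinate frame.

    Only positions where both consensuses are non-N are compared; the
    comparable length L is the shared span minus masked tracts and
    positions no-called in either input. Returns (records, L).
    """
    if not a.region.overlaps(b.region):
        raise ValueError("consensus regions are disjoint")
    region = GenomicRegion(
        a.region.chrom, max(a.region.start, b.region.start), min(a.region.end, b.region.end)
    )
    calls_b = {int(p): c for p, c in zip(b.positions, b.calls)}
    masked = _merge_intervals(list(a.masked) + list(b.masked))
    mask_bp = sum(
        max(0, min(r.end, region.end) - max(r.start, region.start)) for r in masked
    )
    records: list[VariantRecord] = []
    site_excl = 0
    seen = set()
    for pos, call_a in zip(a.positions, a.calls):
        pos = int(pos)
        if not region.contains(pos):
            continue
        seen.add(pos)
        call_b = calls_b.get(pos, call_a if call_a == NOCALL_ALLELE else None)
        if call_b is None:
            # position absent from b: b is implicitly reference there; treat
            # a's call as the difference only if a is non-N and non-ref is
            # unknowable -> skip (sparse representations must share frames)
            call_b = call_a
        if call_a == NOCALL_ALLELE or call_b == NOCALL_ALLELE:
            if not any(t.contains(pos) for t in masked):
                site_excl += 1
            continue
        if call_a != call_b:
            records.append(
                VariantRecord(
                    pos=pos,
                    ref=call_a,
                    alt=call_b,
                    vtype=variant_type_of(call_a, call_b),
                    support=2,
                    called=True,
                )
            )
    for pos, call_b in calls_b.items():
        if pos in seen or not region.contains(pos):
            continue
        if call_b == NOCALL_ALLELE and not any(t.contains(pos) for t in masked):
            site_excl += 1
    L = region.length - mask_bp - site_excl
    return records, L


@dataclass
class SharedSegment:
    start_index: int
    end_index: int  # exclusive
    n_match: int
    n_total: int
    region: Optional[GenomicRegion] = None


def shared_segment_scan(
    query: Sequence,
    ref_a: Sequence,
    ref_b: Optional[Sequence] = None,
    max_mismatch: int = 2,
    positions: Optional[Sequence[int]] = None,
    chrom: str = "chr6",
) -> list[SharedSegment]:
    """Find maximal SNP-index runs with at most ``max_mismatch`` mismatches.

    A SNP matches when the query allele equals ref_a's (and ref_b's, when
    given). Returns every maximal run (no valid run strictly contains
    another reported run), with match counts and, when ``positions`` are
    supplied, the bp span covered.
    """
    q = list(query)
    if len(q) != len(ref_a) or (ref_b is not None and len(ref_b) != len(q)):
        raise ValueError("vectors must have equal length")
    match = [
        q[i] == ref_a[i] and (ref_b is None or q[i] == ref_b[i])
        for i in range(len(q))
    ]
    n = len(match)
    if n == 0:
        return []
    segments: list[tuple[int, int]] = []
    left = 0
    mismatches: list[int] = []
    for r in range(n):
        if not match[r]:
            mismatches.append(r)
            recent = [i for i in mismatches if i >= left]
            if len(recent) > max_mismatch:
                segments.append((left, r))  # [left, r) excludes the new mismatch
                left = recent[0] + 1
    segments.append((left, n))
    maximal = [
        (a, b)
        for a, b in segments
        if b > a
        and not any(
            (c, d) != (a, b) and c <= a and b <= d for c, d in segments
        )
    ]
    out = []
    for a, b in maximal:
        n_match = sum(match[a:b])
        seg = SharedSegment(start_index=a, end_index=b, n_match=n_match, n_total=b - a)
        if positions is not None:
            seg.region = GenomicRegion(chrom, int(positions[a]), int(positions[b - 1]) + 1)
        out.append(seg)
    return out
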