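"""Zygosity profiling, conserved-stretch calling, and ROH scanning.

The segmentation statistic is the per-window zygosity SNV ratio: the number
of homozygous variant SNV calls over the total number of variant SNV calls
in the window. Conserved stretches are maximal runs of windows containing
no more than ``max_fail_run`` consecutive windows with a defined ratio
below ``ratio_min``; windows without variant calls pass (absence of
variants is evidence of conservation). Windows are anchored at the analysis
region start.

The ROH scanner is a from-scratch implementation honoring four bp-scale
parameters: a sliding window (50 kb) in which at most ``max_het_per_window``
heterozygous calls may fall, a maximum inter-site gap (50 kb), and a
minimum reported segment length (1000 kb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Confidence, DiploidCallset, GenomicRegion

NO_DATA = float("nan")


@dataclass
class WindowProfile:
    window: GenomicRegion
    n_hom: int = 0
    n_het: int = 0
    n_snv: int = 0
    n_indel: int = 0

    @property
    def zygosity_ratio(self) -> float:
        """n_hom / (n_hom + n_het); NaN when the window holds no counted calls."""
        total = self.n_hom + self.n_het
        return self.n_hom / total if total else NO_DATA


@dataclass
class ConservedStretch:
    region: GenomicRegion
    n_windows: int
    n_failing_windows: int
    pct_homozygous: float


def window_zygosity_profile(
    callset: DiploidCallset,
    window_size: int = 5_000,
    include_indels: bool = False,
) -> list[WindowProfile]:
    """Tile the callset region with fixed windows and count variant calls.

    Only high-confidence calls where at least one allele differs from the
    reference are counted; by default the hom/het tallies cover SNVs only
    (``include_indels=True`` adds indel calls to them).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    region = callset.region
    n_windows = math.ceil(region.length / window_size)
    profiles = [
        WindowProfile(
            window=GenomicRegion(
                region.chrom,
                region.start + i * window_size,
                min(region.start + (i + 1) * window_size, region.end),
            )
        )
        for i in range(n_windows)
    ]
    for call in callset.calls:
        if call.confidence != Confidence.HIGH or not call.is_variant:
            continue
        w = profiles[(call.pos - region.start) // window_size]
        if call.is_snv:
            w.n_snv += 1
        else:
            w.n_indel += 1
        if call.is_snv or include_indels:
            if call.is_hom:
                w.n_hom += 1
            else:
                w.n_het += 1
    return profiles


def call_conserved_stretches(
    profiles: Sequence[WindowProfile],
    ratio_min: float = 0.95,
    max_fail_run: int = 4,
    min_length: int = 0,
) -> list[ConservedStretch]:
    """Segment window profiles into conserved stretches.

    A window fails iff its ratio is defined and below ``ratio_min``; runs of
    more than ``max_fail_run`` consecutive failing windows split stretches.
    Stretch boundaries are trimmed to the outermost passing windows, and
    stretches shorter than ``min_length`` bp are dropped.
    """
    if not profiles:
        return []
    for a, b in zip(profiles, profiles[1:]):
        if a.window.end != b.window.start or a.window.chrom != b.window.chrom:
            raise ValueError("window profiles must be contiguous and ordered")
    fails = [
        (not math.isnan(p.zygosity_ratio)) and p.zygosity_ratio < ratio_min
        for p in profiles
    ]
    # breakers: runs of > max_fail_run consecutive failing windows
    breaker = [False] * len(profiles)
    i = 0
    while i < len(profiles):
        if fails[i]:
            j = i
            while j < len(profiles) and fails[j]:
                j += 1
            if j - i > max_fail_run:
                for k in range(i, j):
                    breaker[k] = True
            i = j
        else:
            i += 1
    stretches: list[ConservedStretch] = []
    i = 0
    while i < len(profiles):
        if breaker[i]:
            i += 1
            continue
        j = i
        while j < len(profiles) and not breaker[j]:
            j += 1
        # trim leading/trailing failing windows
        a, b = i, j - 1
        while a <= b and fails[a]:
            a += 1
        while b >= a and fails[b]:
            b -= 1
        if a <= b:
            region = GenomicRegion(
                profiles[a].window.chrom,
                profiles[a].window.start,
                profiles[b].window.end,
            )
            if region.length >= min_length:
                n_hom = sum(p.n_hom for p in profiles[a : b + 1])
                n_tot = n_hom + sum(p.n_het for p in profiles[a : b + 1])
                stretches.append(
                    ConservedStretch(
                        region=region,
                        n_windows=b - a + 1,
                        n_failing_windows=sum(fails[a : b + 1]),
                        pct_homozygous=n_hom / n_tot if n_tot else 1.0,
                    )
                )
        i = j
    return stretches


def roh_scan(
    callset: DiploidCallset,
    window: int = 50_000,
    max_het_per_window: int = 3,
    max_gap: int = 50_000,
    min_length: int = 1_000_000,
) -> list[GenomicRegion]:
    """Scan genotyped sites for runs of homozygosity.

    Reports maximal site runs in which no sliding window of ``window`` bp
    contains more than ``max_het_per_window`` heterozygous calls and no two
    adjacent sites are more than ``max_gap`` bp apart; runs spanning at
    least ``min_length`` bp are returned as half-open regions from the first
    to one past the last site of the run.
    """
    sites = [c for c in callset.calls if c.confidence != Confidence.NOCALL]
    if not sites:
        return []
    pos = np.array([c.pos for c in sites])
    het = np.array([c.is_het for c in sites])
    n = len(sites)
    segments: list[tuple[int, int]] = []  # inclusive site-index ranges
    left = 0
    het_idx: list[int] = []  # het site indices with index >= left
    k = max_het_per_window + 1
    for r in range(n):
        if r > 0 and pos[r] - pos[r - 1] > max_gap:
            segments.append((left, r - 1))
            left = r
            het_idx = [i for i in het_idx if i >= left]
        if het[r]:
            het_idx.append(r)
            recent = [i for i in het_idx if i >= left]
            if len(recent) >= k and pos[recent[-1]] - pos[recent[-k]] < window:
                # the violating k-tuple cannot be wholly contained: close the
                # maximal segment ending just before its last member
                segments.append((left, r - 1))
                left = recent[-k] + 1
    segments.append((left, n - 1))
    out = []
    for a, b in segments:
        if b < a:
            continue
        region = GenomicRegion(callset.region.chrom, int(pos[a]), int(pos[b]) + 1)
        if region.length >= min_length:
            out.append(region)
    # drop segments contained in another (can arise from repeated trimming)
    maximal = [
        r
        for r in out
        if not any(
            o is not r and o.start <= r.start and r.end <= o.end for o in out
        )
    ]
    return maximal


def major_allele_frequency_profile(
    haplotypes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site frequency of the most common allele in a haplotype matrix.

    ``haplotypes`` is (n_hap, n_sites) of symbols (any dtype). Returns
    (frequencies, tie_flags); a site where the top two allele counts tie
    reports 0.5 with its flag set.
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2 or h.size == 0:
        raise ValueError("haplotype matrix must be non-empty and 2-D")
    n_hap, n_sites = h.shape
    freqs = np.empty(n_sites)
    ties = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        _, counts = np.unique(h[:, j], return_counts=True)
        counts = np.sort(counts)[::-1]
        if len(counts) > 1 and counts[0] == counts[1]:
            freqs[j], ties[j] = 0.5, True
        else:
            freqs[j] = counts[0] / n_hap
    return freqs, ties


def genotype_concordance(
    a: DiploidCallset, b: DiploidCallset
) -> tuple[int, int, float]:
    """Concordance between two call sets of the same sample.

    Compared only at positions called high-confidence in both; a position is
    concordant iff the unordered allele pairs are equal. Returns
    (n_compared, n_concordant, rate); rate is NaN with nothing to compare.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(
            f"sample mismatch: {a.sample_id!r} vs {b.sample_id!r}"
        )
    calls_b = {
        c.pos: c for c in b.calls if c.confidence == Confidence.HIGH
    }
    n_cmp = n_conc = 0
    for ca in a.calls:
        if ca.confidence != Confidence.HIGH:
            continue
        cb = calls_b.get(ca.pos)
        if cb is None:
            continue
        n_cmp += 1
        if sorted(ca.alleles) == sorted(cb.alleles):
            n_conc += 1
    return n_cmp, n_conc, (n_conc / n_cmp if n_cmp else NO_DATA)
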