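"""Pairwise r² LD, block detection, block haplotype tables, co-segregation
screening, and ΔCt expression quantification.

An LD block is a maximal contiguous SNP run in which every pairwise r²
exceeds the threshold (strictly; default 0.8). Block search is greedy left
to right: the leftmost maximal run wins and the remaining sites are
re-scanned to its right, which makes the partition deterministic.

Haplotype matrices are phased, {0,1}-coded, one chromosome per row;
missing entries are coded -1 and handled pairwise-complete in r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MISSING = -1


@dataclass
class LDResult:
    i: int
    j: int
    p_a: float  # frequency of allele 1 at site i
    p_b: float  # frequency of allele 1 at site j
    D: float
    r2: float
    n_complete: int
    defined: bool


def pairwise_r2(haplotypes: np.ndarray, i: int, j: int) -> LDResult:
    """r² between sites i and j over pairwise-complete chromosomes.

    D = p_AB - p_A * p_B and r² = D² / (p_A q_A p_B q_B); a pair with a
    monomorphic site (or no complete rows) is flagged undefined.
    """
    if i == j:
        raise ValueError("sites must differ")
    h = np.asarray(haplotypes)
    if h.shape[0] < 2:
        raise ValueError("need at least two haplotypes")
    a, b = h[:, i], h[:, j]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    n = len(a)
    if n == 0:
        return LDResult(i, j, float("nan"), float("nan"), float("nan"), float("nan"), 0, False)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(i, j, p_a, p_b, float("nan"), float("nan"), n, False)
    p_ab = np.mean(a * b)
    D = p_ab - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(i, j, float(p_a), float(p_b), float(D), float(r2), n, True)


def r2_matrix(haplotypes: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise r² (NaN where undefined)."""
    n_sites = np.asarray(haplotypes).shape[1]
    m = np.full((n_sites, n_sites), np.nan)
    np.fill_diagonal(m, 1.0)
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            res = pairwise_r2(haplotypes, i, j)
            m[i, j] = m[j, i] = res.r2 if res.defined else np.nan
    return m


@dataclass
class LDBlock:
    start_index: int
    end_index: int  # exclusive
    min_r2: float
    haplotype_freqs: dict[str, float] = field(default_factory=dict)
    crossover_links: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index


def find_ld_blocks(haplotypes: np.ndarray, r2_min: float = 0.8) -> list[LDBlock]:
    """Greedy left-to-right detection of all-pairs r² blocks.

    A block requires every pairwise r² among its sites to be defined and
    strictly above ``r2_min``; singleton sites are not reported.
    """
    h = np.asarray(haplotypes)
    n_sites = h.shape[1]
    r2 = r2_matrix(h)
    blocks: list[LDBlock] = []
    i = 0
    while i < n_sites:
        j = i
        # extend while site j+1 stays above threshold with every block member
        while j + 1 < n_sites and all(
            np.isfinite(r2[k, j + 1]) and r2[k, j + 1] > r2_min
            for k in range(i, j + 1)
        ):
            j += 1
        if j > i:
            pairs = [r2[a, b] for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            blocks.append(
                LDBlock(start_index=i, end_index=j + 1, min_r2=float(min(pairs)))
            )
            i = j + 1
        else:
            i += 1
    return blocks


def block_haplotype_table(
    haplotypes: np.ndarray,
    block: LDBlock,
    next_block: Optional[LDBlock] = None,
) -> LDBlock:
    """Fill a block's haplotype frequency table and crossover links.

    Frequencies count the distinct within-block haplotype strings; link
    weight (h1 -> h2) is the conditional fraction of chromosomes carrying
    h1 in this block that carry h2 in the next, so in the absence of
    recombination the link matrix is a permutation. Rows with missing
    entries are an error (the operation assumes phased, complete input).
    """
    h = np.asarray(haplotypes)
    sub = h[:, block.start_index : block.end_index]
    if np.any(sub == MISSING):
        raise ValueError("block haplotype table requires phased, complete input")
    strings = ["".join(str(int(x)) for x in row) for row in sub]
    n = len(strings)
    freqs: dict[str, float] = {}
    for s in strings:
        freqs[s] = freqs.get(s, 0.0) + 1.0 / n
    block.haplotype_freqs = dict(sorted(freqs.items(), key=lambda kv: -kv[1]))
    if next_block is not None:
        nxt = h[:, next_block.start_index : next_block.end_index]
        if np.any(nxt == MISSING):
            raise ValueError("block haplotype table requires phased, complete input")
        nxt_strings = ["".join(str(int(x)) for x in row) for row in nxt]
        joint: dict[tuple[str, str], int] = {}
        carrier: dict[str, int] = {}
        for s1, s2 in zip(strings, nxt_strings):
            joint[(s1, s2)] = joint.get((s1, s2), 0) + 1
            carrier[s1] = carrier.get(s1, 0) + 1
        block.crossover_links = {
            (s1, s2): c / carrier[s1] for (s1, s2), c in sorted(joint.items())
        }
    return block


def cosegregation_screen(
    alleles: np.ndarray,
    phenotype: Sequence[bool],
    site_ids: Optional[Sequence] = None,
) -> list:
    """Sites whose alleles perfectly partition a binary phenotype.

    ``alleles`` is (n_sites, n_samples) of allele symbols (any dtype); a
    site is a candidate iff the allele sets of the two phenotype classes do
    not overlap. Returns site ids (row indices by default).
    """
    a = np.asarray(alleles)
    pheno = np.asarray(phenotype, dtype=bool)
    if a.shape[1] != len(pheno):
        raise ValueError("allele matrix and phenotype length mismatch")
    if pheno.all() or not pheno.any():
        raise ValueError("phenotype must contain both classes")
    ids = list(site_ids) if site_ids is not None else list(range(a.shape[0]))
    out = []
    for s in range(a.shape[0]):
        pos_alleles = set(a[s, pheno].tolist())
        neg_alleles = set(a[s, ~pheno].tolist())
        if not (pos_alleles & neg_alleles):
            out.append(ids[s])
    return out


def delta_ct_expression(
    ct_target: Sequence[float],
    ct_ref: Sequence[float],
    detect_limit: float = 35.0,
) -> tuple[float, bool]:
    """Relative expression 2^-(mean dCt) with a detection-limit call.

    Target replicates at/above ``detect_limit`` or recorded as the
    no-amplification sentinel (NaN) count as undetected; when no target
    replicate is detected, expression is 0 and the expressed flag False.
    """
    t = np.asarray(list(ct_target), dtype=float)
    r = np.asarray(list(ct_ref), dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("need at least one replicate for target and reference")
    detected = t[np.isfinite(t) & (t < detect_limit)]
    if detected.size == 0:
        return 0.0, False
    ref = r[np.isfinite(r)]
    if ref.size == 0:
        raise ValueError("reference gene did not amplify")
    d_ct = detected.mean() - ref.mean()
    return float(2.0 ** (-d_ct)), True
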