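"""SNP alignments, Kimura 2-parameter distances, NJ trees, and bootstrap.

Heterozygous and no-called genotypes enter the alignment as missing
symbols; distances use pairwise deletion, and the bootstrap resamples
alignment columns (missing data travels with its column). Tree topology
comes from neighbor joining on the K2P distance matrix — a distance-based
substitute for likelihood tree search that gives identical groupings for
near-clonal haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .consensus import ConsensusHaplotype
from .core import Confidence, DiploidCallset

MISSING = "?"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
SATURATED = float("inf")


@dataclass
class SnpAlignment:
    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites) of single-character symbols
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="U1")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment shape must be (n_taxa, n_sites)")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]


def build_snp_alignment(
    inputs: Sequence[Union[DiploidCallset, ConsensusHaplotype]],
    sites: Sequence[int],
) -> SnpAlignment:
    """Project call sets / consensus haplotypes onto a common SNP site list.

    Homozygous diploid calls contribute their allele; heterozygous calls,
    no-calls, and sites absent from an input become the missing symbol.
    """
    sites = list(sites)
    taxa, rows = [], []
    for obj in inputs:
        row = [MISSING] * len(sites)
        index = {int(s): k for k, s in enumerate(sites)}
        if isinstance(obj, DiploidCallset):
            taxa.append(obj.sample_id)
            for c in obj.calls:
                k = index.get(c.pos)
                if k is None:
                    continue
                if (
                    c.confidence == Confidence.HIGH
                    and c.is_hom
                    and c.alleles[0] in "ACGT"
                ):
                    row[k] = c.alleles[0]
        else:
            taxa.append(obj.name)
            for pos, call in zip(obj.positions, obj.calls):
                k = index.get(int(pos))
                if k is not None and call in "ACGT":
                    row[k] = call
        rows.append(row)
    return SnpAlignment(
        taxa=taxa, data=np.array(rows, dtype="U1"), positions=np.array(sites)
    )


@dataclass
class K2PResult:
    P: float  # transition proportion
    Q: float  # transversion proportion
    n_compared: int
    d: float
    defined: bool


def k2p_distance(a: Sequence[str], b: Sequence[str]) -> K2PResult:
    """Kimura 2-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are transition and transversion proportions over
    pairwise-complete sites; saturation (non-positive log argument) yields
    a flagged infinite distance.
    """
    aa = np.asarray(list(a), dtype="U1")
    bb = np.asarray(list(b), dtype="U1")
    if aa.shape != bb.shape:
        raise ValueError("sequences must have equal length")
    valid = np.isin(aa, list("ACGT")) & np.isin(bb, list("ACGT"))
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no pairwise-complete sites")
    x, y = aa[valid], bb[valid]
    diff = x != y
    transitions = sum(
        1
        for u, v in zip(x[diff], y[diff])
        if {u, v} <= PURINES or {u, v} <= PYRIMIDINES
    )
    P = transitions / n
    Q = (int(diff.sum()) - transitions) / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P=P, Q=Q, n_compared=n, d=SATURATED, defined=False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(P=P, Q=Q, n_compared=n, d=d, defined=True)


def k2p_matrix(aln: SnpAlignment, saturated_distance: float = 5.0) -> DistanceMatrix:
    """All-pairs K2P distances; saturated pairs take ``saturated_distance``."""
    n = len(aln.taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(aln.data[i], aln.data[j])
            m[i, j] = m[j, i] = res.d if res.defined else saturated_distance
    return DistanceMatrix(m, ids=aln.taxa)


def nj_tree(dm: Union[DistanceMatrix, np.ndarray], ids: Optional[Sequence[str]] = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm), ids=list(ids) if ids else None)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    return nj(dm)


def tree_splits(tree: TreeNode, taxa: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions, canonicalized to the side without taxa[0]."""
    all_taxa = frozenset(taxa)
    anchor = sorted(all_taxa)[0]
    splits = set()
    for subset in tree.subsets():
        side = frozenset(subset)
        if anchor in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            splits.add(side)
    return splits


def to_newick(tree: TreeNode, support: Optional[dict[frozenset[str], float]] = None) -> str:
    """Newick string with branch lengths to 6 decimals and optional support
    percentages as internal node labels."""
    t = tree.copy()
    taxa = [tip.name for tip in t.tips()]
    for node in t.non_tips(include_self=False):
        if node.length is not None:
            node.length = round(max(node.length, 0.0), 6)
        if support is not None:
            side = frozenset(tip.name for tip in node.tips())
            anchor = sorted(taxa)[0]
            canonical = side if anchor not in side else frozenset(taxa) - side
            if canonical in support:
                node.name = f"{support[canonical]:.0f}"
    for tip in t.tips():
        if tip.length is not None:
            tip.length = round(max(tip.length, 0.0), 6)
    return str(t).strip()


def bootstrap_support(
    aln: SnpAlignment,
    n_reps: int = 500,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Percentage of column-resampled NJ replicates containing each split
    of the original tree."""
    if len(aln.taxa) < 4:
        raise ValueError("bootstrap requires at least four taxa")
    base_tree = nj_tree(k2p_matrix(aln))
    base_splits = tree_splits(base_tree, aln.taxa)
    counts = {s: 0 for s in base_splits}
    if n_reps == 0:
        return {}
    rng = np.random.default_rng(seed)
    n_sites = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = SnpAlignment(taxa=aln.taxa, data=aln.data[:, cols])
        try:
            rep_splits = tree_splits(nj_tree(k2p_matrix(rep)), aln.taxa)
        except ValueError:
            continue
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n_reps for s, c in counts.items()}
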