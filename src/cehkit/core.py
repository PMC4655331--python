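"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open everywhere inside the package; the
1-based convention of VCF is converted at the I/O boundary only.

Allele tokens: single bases ``A/C/G/T``, the no-call symbol ``N``,
``ins:<seq>`` for an insertion of ``<seq>`` after the anchor position, and
``del:<n>`` for a deletion of ``<n>`` reference bases starting at the
position. Indels are stored left-aligned in minimal representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

BASES = ("A", "C", "G", "T")
NOCALL_ALLELE = "N"


class Confidence(str, Enum):
    """Three-level call confidence: high-quality, low-confidence, or no-call."""

    HIGH = "high"
    LOW = "low"
    NOCALL = "nocall"


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def is_indel_token(allele: str) -> bool:
    return allele.startswith("ins:") or allele.startswith("del:")


@dataclass
class SiteCall:
    """Diploid call at a single position.

    ``alleles`` is the ordered pair of observed alleles; when ``phased`` is
    True the order is chromosomal (first allele -> chromosome 0). A no-call
    carries ``(N, N)``.
    """

    pos: int
    ref: str
    alleles: tuple[str, str]
    confidence: Confidence = Confidence.HIGH
    phased: bool = False

    def __post_init__(self) -> None:
        if self.confidence == Confidence.NOCALL and self.alleles != (
            NOCALL_ALLELE,
            NOCALL_ALLELE,
        ):
            raise ValueError("no-call sites must carry (N, N) alleles")

    @property
    def is_het(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return not self.is_het

    @property
    def is_variant(self) -> bool:
        """At least one non-N allele differs from the reference allele."""
        return any(a != self.ref and a != NOCALL_ALLELE for a in self.alleles)

    @property
    def is_snv(self) -> bool:
        return self.is_variant and not any(
            is_indel_token(a) for a in self.alleles if a != self.ref
        )

    @property
    def is_indel(self) -> bool:
        return self.is_variant and not self.is_snv


@dataclass
class DiploidCallset:
    """Position-sorted diploid calls for one sample over one region.

    ``masked`` optionally lists fully no-called tracts (e.g. assembly gaps)
    that have no per-site representation; they are excluded from comparable
    length in downstream comparisons.
    """

    sample_id: str
    region: GenomicRegion
    calls: list[SiteCall] = field(default_factory=list)
    masked: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = -1
        for c in self.calls:
            if c.pos <= last:
                raise ValueError("calls must be strictly increasing in position")
            if not self.region.contains(c.pos):
                raise ValueError(f"call at {c.pos} outside region {self.region}")
            last = c.pos

    def positions(self) -> list[int]:
        return [c.pos for c in self.calls]


@dataclass
class ReferenceTrack:
    """Reference sequence over a region; index by absolute genomic position."""

    region: GenomicRegion
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region.length:
            raise ValueError("sequence length must equal region length")

    def base(self, pos: int) -> str:
        if not self.region.contains(pos):
            raise IndexError(f"position {pos} outside reference region")
        return self.sequence[pos - self.region.start]

    def slice(self, start: int, end: int) -> str:
        return self.sequence[start - self.region.start : end - self.region.start]


@dataclass
class GeneModel:
    """Transcript model with CDS segments carrying cumulative frame offsets."""

    gene: str
    strand: str
    tx: GenomicRegion
    exons: list[GenomicRegion] = field(default_factory=list)
    cds_segments: list[tuple[GenomicRegion, int]] = field(default_factory=list)
    utr5: list[GenomicRegion] = field(default_factory=list)
    utr3: list[GenomicRegion] = field(default_factory=list)
    is_ncRNA: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


class VariantType(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


class ZygosityForm(str, Enum):
    """How the alternate allele sits within its carrier individual(s)."""

    HETEROZYGOUS = "heterozygous-within-individual"
    HOMOZYGOUS = "homozygous-within-individual"
    MIXED = "mixed"


@dataclass
class VariantRecord:
    pos: int
    ref: str
    alt: str
    vtype: VariantType
    support: int = 1
    zygosity_form: Optional[ZygosityForm] = None
    called: bool = False
    feature_class: Optional[str] = None
    known: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


def variant_type_of(ref: str, alt: str) -> VariantType:
    if alt.startswith("ins:"):
        return VariantType.INSERTION
    if alt.startswith("del:"):
        return VariantType.DELETION
    return VariantType.SNV
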