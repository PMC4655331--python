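"""Readers and writers for the formats the pipeline touches.

VCF reading goes through cyvcf2; everything downstream consumes the typed
containers from :mod:`cehkit.core` and never re-parses files. BED output is
0-based half-open. Gene models come from BED12 (thickStart/thickEnd marking
the CDS) or a small GFF-lite TSV with columns
``gene  chrom  strand  feature  start  end`` where ``feature`` is one of
``exon``/``CDS`` (start/end 0-based half-open).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

from cyvcf2 import VCF

from .core import (
    Confidence,
    DiploidCallset,
    GeneModel,
    GenomicRegion,
    NOCALL_ALLELE,
    ReferenceTrack,
    SiteCall,
)

logger = logging.getLogger("cehkit")


class FormatError(ValueError):
    pass


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align a REF/ALT pair to minimal representation and token form.

    Returns ``(pos, ref_token, alt_token)`` where SNVs keep single bases and
    indels become ``ins:<seq>`` / ``del:<n>`` tokens anchored at ``pos``.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim shared suffix, then shared prefix (advancing pos)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    if len(ref) < len(alt) and alt.startswith(ref):
        return pos, ref[0], f"ins:{alt[len(ref):]}"
    if len(alt) < len(ref) and ref.startswith(alt):
        # deletion anchored just after the retained base
        return pos, ref[0], f"del:{len(ref) - len(alt)}"
    # complex substitution: keep as-is, classified downstream by length
    return pos, ref, alt


def read_vcf_subset(path: str | Path, region: GenomicRegion) -> list[DiploidCallset]:
    """Read a VCF (v4.x, GT fields) into one callset per sample.

    1-based VCF positions are shifted to internal 0-based coordinates;
    FILTER values other than PASS/"." map to low confidence; missing
    genotypes (./.) map to no-calls; the ``|`` separator marks phased calls.
    A region with no overlapping records yields empty callsets.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} carries no sample columns")
    per_sample: dict[str, list[SiteCall]] = {s: [] for s in samples}
    for var in vcf:
        pos0 = var.POS - 1
        if var.CHROM != region.chrom or not region.contains(pos0):
            continue
        base_conf = Confidence.HIGH if var.FILTER is None else Confidence.LOW
        alts = var.ALT or []
        tokens: dict[int, tuple[int, str, str]] = {}
        for idx, alt in enumerate(alts, start=1):
            tokens[idx] = normalize_variant(pos0, var.REF, alt)
        for si, sample in enumerate(samples):
            g = var.genotypes[si]
            a_idx, b_idx, phased = g[0], g[1], bool(g[-1])
            if a_idx < 0 or b_idx < 0:
                call = SiteCall(
                    pos=pos0,
                    ref=var.REF[0].upper(),
                    alleles=(NOCALL_ALLELE, NOCALL_ALLELE),
                    confidence=Confidence.NOCALL,
                )
            else:
                pair = []
                norm_pos = pos0
                ref_token = var.REF[0].upper()
                for ai in (a_idx, b_idx):
                    if ai == 0:
                        pair.append(None)  # placeholder: ref allele token
                    else:
                        p, r, a = tokens[ai]
                        norm_pos, ref_token = p, r
                        pair.append(a)
                alleles = tuple(ref_token if a is None else a for a in pair)
                call = SiteCall(
                    pos=norm_pos,
                    ref=ref_token,
                    alleles=alleles,  # type: ignore[arg-type]
                    confidence=base_conf,
                    phased=phased,
                )
            per_sample[sample].append(call)
    callsets = []
    for sample in samples:
        calls = sorted(per_sample[sample], key=lambda c: c.pos)
        callsets.append(DiploidCallset(sample_id=sample, region=region, calls=calls))
    return callsets


def _token_to_vcf(pos: int, ref_base: str, allele: str) -> tuple[str, str]:
    if allele.startswith("ins:"):
        return ref_base, ref_base + allele[4:]
    if allele.startswith("del:"):
        n = int(allele[4:])
        return ref_base + "N" * n, ref_base
    return ref_base, allele


def write_vcf(
    path: str | Path,
    callsets: Sequence[DiploidCallset],
    reference: Optional[ReferenceTrack] = None,
) -> None:
    """Write callsets sharing one region to a minimal multi-sample VCF."""
    if not callsets:
        raise ValueError("need at least one callset")
    region = callsets[0].region
    by_pos: dict[int, dict[str, SiteCall]] = {}
    for cs in callsets:
        if cs.region != region:
            raise ValueError("all callsets must share one region")
        for c in cs.calls:
            by_pos.setdefault(c.pos, {})[cs.sample_id] = c
    samples = [cs.sample_id for cs in callsets]
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={region.chrom}>",
        '##FILTER=<ID=LowQual,Description="Low confidence call">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos in sorted(by_pos):
        calls = by_pos[pos]
        ref_base = next(iter(calls.values())).ref
        if reference is not None and not ref_base.startswith(("i", "d")):
            ref_base = reference.base(pos)
        alts: list[str] = []
        vcf_ref = ref_base
        filt = "PASS"
        gts = []
        for s in samples:
            c = calls.get(s)
            if c is None:
                gts.append("0/0")
                continue
            if c.confidence == Confidence.NOCALL:
                gts.append("./.")
                continue
            if c.confidence == Confidence.LOW:
                filt = "LowQual"
            idxs = []
            for a in c.alleles:
                if a == c.ref:
                    idxs.append(0)
                else:
                    r, alt_seq = _token_to_vcf(pos, c.ref, a)
                    vcf_ref = r if len(r) > len(vcf_ref) else vcf_ref
                    if alt_seq not in alts:
                        alts.append(alt_seq)
                    idxs.append(alts.index(alt_seq) + 1)
            sep = "|" if c.phased else "/"
            gts.append(f"{idxs[0]}{sep}{idxs[1]}")
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{region.chrom}\t{pos + 1}\t.\t{vcf_ref}\t{alt_field}\t.\t{filt}\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicRegion],
    labels: Optional[Sequence[str]] = None,
) -> None:
    """Write sorted intervals as BED3 (or BED4 when labels are given)."""
    prev: Optional[GenomicRegion] = None
    rows = []
    for i, iv in enumerate(intervals):
        if prev is not None and iv.chrom == prev.chrom and iv.start < prev.start:
            raise ValueError("intervals must be sorted per chromosome")
        prev = iv
        row = f"{iv.chrom}\t{iv.start}\t{iv.end}"
        if labels is not None:
            row += f"\t{labels[i]}"
        rows.append(row)
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_bed(path: str | Path) -> tuple[list[GenomicRegion], list[str]]:
    intervals, labels = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        intervals.append(GenomicRegion(f[0], int(f[1]), int(f[2])))
        labels.append(f[3] if len(f) > 3 else "")
    return intervals, labels


def _frames(segments: list[GenomicRegion], strand: str) -> list[tuple[GenomicRegion, int]]:
    ordered = segments if strand == "+" else list(reversed(segments))
    out, cum = [], 0
    for seg in ordered:
        out.append((seg, cum % 3))
        cum += seg.length
    return out if strand == "+" else list(reversed(out))


def _finish_model(
    gene: str,
    chrom: str,
    strand: str,
    exons: list[GenomicRegion],
    cds: list[GenomicRegion],
) -> GeneModel:
    exons = sorted(exons, key=lambda r: r.start)
    cds = sorted(cds, key=lambda r: r.start)
    tx = GenomicRegion(chrom, exons[0].start, exons[-1].end)
    is_nc = not cds
    cds_len = sum(s.length for s in cds)
    if cds and cds_len % 3 != 0:
        warnings.warn(
            f"gene {gene}: CDS length {cds_len} not divisible by 3; "
            "treated as non-coding for effect annotation"
        )
        is_nc, cds = True, []
    utr5: list[GenomicRegion] = []
    utr3: list[GenomicRegion] = []
    if cds:
        cds_start, cds_end = cds[0].start, cds[-1].end
        for ex in exons:
            if ex.start < cds_start:
                seg = GenomicRegion(chrom, ex.start, min(ex.end, cds_start))
                (utr5 if strand == "+" else utr3).append(seg)
            if ex.end > cds_end:
                seg = GenomicRegion(chrom, max(ex.start, cds_end), ex.end)
                (utr3 if strand == "+" else utr5).append(seg)
    return GeneModel(
        gene=gene,
        strand=strand,
        tx=tx,
        exons=exons,
        cds_segments=_frames(cds, strand) if cds else [],
        utr5=utr5,
        utr3=utr3,
        is_ncRNA=is_nc,
    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or GFF-lite TSV (sniffed by column count)."""
    path = Path(path)
    lines = [
        l for l in path.read_text().splitlines() if l.strip() and not l.startswith("#")
    ]
    if not lines:
        return []
    ncol = len(lines[0].split("\t"))
    if ncol == 12:
        return [_model_from_bed12(l) for l in lines]
    if ncol == 6:
        return _models_from_gff_lite(lines)
    raise FormatError(f"{path}: expected 12 (BED12) or 6 (GFF-lite) columns, got {ncol}")


def _model_from_bed12(line: str) -> GeneModel:
    f = line.split("\t")
    chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
    strand = f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [
        GenomicRegion(chrom, start + o, start + o + s) for o, s in zip(offsets, sizes)
    ]
    cds = []
    if thick_end > thick_start:
        for ex in exons:
            s, e = max(ex.start, thick_start), min(ex.end, thick_end)
            if e > s:
                cds.append(GenomicRegion(chrom, s, e))
    return _finish_model(name, chrom, strand, exons, cds)


def _models_from_gff_lite(lines: list[str]) -> list[GeneModel]:
    grouped: dict[str, dict] = {}
    for line in lines:
        gene, chrom, strand, feature, start, end = line.split("\t")
        d = grouped.setdefault(gene, {"chrom": chrom, "strand": strand, "exon": [], "cds": []})
        iv = GenomicRegion(chrom, int(start), int(end))
        key = "cds" if feature.upper() == "CDS" else "exon"
        d[key].append(iv)
    models = []
    for gene, d in grouped.items():
        exons = d["exon"] or d["cds"]
        models.append(_finish_model(gene, d["chrom"], d["strand"], exons, d["cds"]))
    return models


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = []
        elif name is not None:
            records[name].append(line.strip())
    return {k: "".join(v) for k, v in records.items()}
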