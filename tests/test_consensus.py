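"""Haploid splitting, consensus rules, catalogues, shared-segment scan."""

import numpy as np
import pytest
from scipy import stats

from cehkit.consensus import (
    build_consensus,
    comparable_length,
    intra_ceh_catalog,
    inter_haplotype_catalog,
    shared_segment_scan,
    split_haploids,
)
from cehkit.core import (
    Confidence,
    DiploidCallset,
    GenomicRegion,
    ReferenceTrack,
    SiteCall,
    VariantType,
    ZygosityForm,
)
from cehkit.simulate import CehSimParams, simulate_ceh_cohort

REGION = GenomicRegion("chr6", 0, 100)


def _cs(sites, sample="S1", region=REGION):
    return DiploidCallset(
        sample_id=sample,
        region=region,
        calls=[
            SiteCall(
                pos=s[0],
                ref=s[1],
                alleles=(s[2], s[3]),
                confidence=s[4] if len(s) > 4 else Confidence.HIGH,
                phased=True,
            )
            for s in sites
        ],
    )


class TestSplitHaploids:
    def test_hom_site_on_both(self):
        h0, h1 = split_haploids(_cs([(1, "A", "A", "A")]))
        assert h0.alleles == ["A"] and h1.alleles == ["A"]

    def test_phased_het_splits_by_phase(self):
        h0, h1 = split_haploids(_cs([(1, "A", "A", "G")]))
        assert (h0.alleles, h1.alleles) == (["A"], ["G"])
        assert not h0.phase_arbitrary[0]

    def test_unphased_het_convention_flagged(self):
        cs = DiploidCallset(
            sample_id="S1",
            region=REGION,
            calls=[SiteCall(pos=1, ref="A", alleles=("G", "A"), phased=False)],
        )
        h0, h1 = split_haploids(cs)
        assert (h0.alleles, h1.alleles) == (["G"], ["A"])
        assert h0.phase_arbitrary[0] and h1.phase_arbitrary[0]

    def test_nocall_propagates_as_n(self):
        cs = DiploidCallset(
            sample_id="S1",
            region=REGION,
            calls=[
                SiteCall(pos=1, ref="A", alleles=("N", "N"), confidence=Confidence.NOCALL)
            ],
        )
        h0, _ = split_haploids(cs)
        assert h0.alleles == ["N"]


def _haploids(allele_rows, ref_seq="A" * 100, confidences=None):
    """Build 6 haploids over positions 0..n-1 from per-haploid allele lists."""
    n_sites = len(allele_rows[0])
    callsets = []
    for k in range(0, len(allele_rows), 2):
        sites = []
        for j in range(n_sites):
            a, b = allele_rows[k][j], allele_rows[k + 1][j]
            conf = confidences[k // 2][j] if confidences else Confidence.HIGH
            if conf == Confidence.NOCALL:
                a = b = "N"
            sites.append(
                SiteCall(pos=j, ref=ref_seq[j], alleles=(a, b), confidence=conf, phased=True)
            )
        callsets.append(
            DiploidCallset(sample_id=f"S{k // 2 + 1}", region=REGION, calls=sites)
        )
    haploids = [h for cs in callsets for h in split_haploids(cs)]
    return haploids, callsets


class TestBuildConsensus:
    REF = ReferenceTrack(region=REGION, sequence="A" * 100)

    def test_singleton_alternate_not_called(self):
        haploids, _ = _haploids([["A"], ["A"], ["A"], ["A"], ["A"], ["G"]])
        result = build_consensus(haploids, reference=self.REF)
        assert result.calls == ["A"]
        (v,) = result.variants
        assert (v.alt, v.support, v.called) == ("G", 1, False)

    def test_two_haploid_alternate_called(self):
        haploids, _ = _haploids([["G"], ["G"], ["A"], ["A"], ["A"], ["A"]])
        result = build_consensus(haploids, reference=self.REF)
        assert result.calls == ["A"]
        (v,) = result.variants
        assert (v.alt, v.support, v.called) == ("G", 2, True)

    def test_two_low_confidence_inputs_nocall(self):
        rows = [["A"], ["A"], ["A"], ["A"], ["A"], ["A"]]
        confs = [[Confidence.HIGH], [Confidence.LOW], [Confidence.LOW]]
        haploids, _ = _haploids(rows, confidences=confs)
        result = build_consensus(haploids, reference=self.REF)
        assert result.calls == ["N"]

    def test_exact_tie_is_ambiguous_nocall(self):
        haploids, _ = _haploids([["G"], ["G"], ["G"], ["A"], ["A"], ["A"]])
        result = build_consensus(haploids)
        assert result.calls == ["N"] and result.ambiguous_positions == [0]

    def test_identity_reproduces_input_with_full_support(self):
        rows = [["A", "C", "G"]] * 6
        haploids, _ = _haploids(rows, ref_seq="ACG" + "A" * 97)
        result = build_consensus(haploids)
        assert result.calls == ["A", "C", "G"]
        assert (result.support == 6).all()

    def test_fewer_than_two_haploids_rejected(self):
        haploids, _ = _haploids([["A"], ["A"]])
        with pytest.raises(ValueError):
            build_consensus(haploids[:1])


class TestIntraCatalog:
    def test_identical_haploids_empty(self):
        haploids, callsets = _haploids([["A", "C"]] * 6, ref_seq="AC" + "A" * 98)
        assert intra_ceh_catalog(haploids, callsets) == []

    def test_singleton_het_recorded(self):
        rows = [["G"], ["A"], ["A"], ["A"], ["A"], ["A"]]
        haploids, callsets = _haploids(rows)
        (v,) = intra_ceh_catalog(haploids, callsets)
        assert (v.ref, v.alt, v.support) == ("A", "G", 1)
        assert v.zygosity_form is ZygosityForm.HETEROZYGOUS
        assert not v.called

    def test_hom_alternate_recorded_as_homozygous_form(self):
        rows = [["G"], ["G"], ["A"], ["A"], ["A"], ["A"]]
        haploids, callsets = _haploids(rows)
        (v,) = intra_ceh_catalog(haploids, callsets)
        assert v.support == 2 and v.zygosity_form is ZygosityForm.HOMOZYGOUS
        assert v.called

    def test_ambiguous_position_excluded(self):
        rows = [["G"], ["A"], ["A"], ["A"], ["A"], ["A"]]
        confs = [[Confidence.LOW], [Confidence.HIGH], [Confidence.HIGH]]
        haploids, callsets = _haploids(rows, confidences=confs)
        assert intra_ceh_catalog(haploids, callsets) == []
        assert comparable_length(REGION, haploids) == 99

    def test_symmetric_under_reordering(self):
        rows = [["G", "A"], ["A", "A"], ["A", "T"], ["A", "A"], ["A", "A"], ["A", "A"]]
        haploids, callsets = _haploids(rows)
        base = intra_ceh_catalog(haploids, callsets)
        perm = [haploids[i] for i in (4, 5, 2, 3, 0, 1)]
        perm_callsets = [callsets[i] for i in (2, 1, 0)]
        again = intra_ceh_catalog(perm, perm_callsets)
        assert [(v.pos, v.ref, v.alt, v.support) for v in base] == [
            (v.pos, v.ref, v.alt, v.support) for v in again
        ]

    def test_simulated_cohort_recovered_exactly(self):
        params = CehSimParams(
            region_length=500_000,
            region_start=0,
            snv_rate=50.0,
            founder_snv_rate=20.0,
            seed=13,
        )
        callsets, reference, truth = simulate_ceh_cohort(params)
        haploids = [h for cs in callsets for h in split_haploids(cs)]
        records = intra_ceh_catalog(haploids, callsets, reference=reference)
        got = {(v.pos, v.alt) for v in records}
        planted = {(v.pos, v.alt) for v in truth.variants}
        assert got == planted
        # founder-vs-reference differences are not intra-CEH variation
        assert not any(
            v.pos in {f.pos for f in truth.founder_variants} for v in records
        )

    def test_brute_force_type_totals_agree(self):
        params = CehSimParams(
            region_length=10_000, region_start=0, snv_rate=300.0, seed=3
        )
        callsets, reference, truth = simulate_ceh_cohort(params)
        haploids = [h for cs in callsets for h in split_haploids(cs)]
        records = intra_ceh_catalog(haploids, callsets, reference=reference)
        n_indel_records = sum(1 for v in records if v.vtype != VariantType.SNV)
        assert n_indel_records == sum(1 for v in truth.variants if v.is_indel)
        assert len(records) == len(truth.variants)


class TestInterCatalog:
    def _consensus(self, alleles, positions=None, name="X"):
        from cehkit.consensus import ConsensusHaplotype

        pos = np.array(positions if positions is not None else range(len(alleles)))
        return ConsensusHaplotype(
            name=name,
            region=REGION,
            positions=pos,
            calls=list(alleles),
            support=np.full(len(alleles), 6),
            ambiguous_positions=[],
        )

    def test_identical_consensuses(self):
        a = self._consensus(["A", "C", "G"])
        b = self._consensus(["A", "C", "G"], name="Y")
        records, L = inter_haplotype_catalog(a, b)
        assert records == [] and L == REGION.length

    def test_snv_and_deletion_difference(self):
        a = self._consensus(["A", "C", "G"])
        b = self._consensus(["G", "C", "del:3"], name="Y")
        records, _ = inter_haplotype_catalog(a, b)
        assert [v.vtype for v in records] == [VariantType.SNV, VariantType.DELETION]

    def test_nocall_positions_shrink_comparable_length(self):
        a = self._consensus(["A", "N", "G"])
        b = self._consensus(["A", "C", "N"], name="Y")
        records, L = inter_haplotype_catalog(a, b)
        assert records == [] and L == REGION.length - 2

    def test_divergence_rate_in_poisson_band(self):
        rng = np.random.default_rng(21)
        region_len = 1_000_000
        n_diff = rng.poisson(2.7e-3 * region_len)
        pos = np.sort(rng.choice(region_len, size=n_diff, replace=False))
        big = GenomicRegion("chr6", 0, region_len)
        from cehkit.consensus import ConsensusHaplotype

        a = ConsensusHaplotype(
            name="A",
            region=big,
            positions=pos,
            calls=["A"] * n_diff,
            support=np.full(n_diff, 6),
            ambiguous_positions=[],
        )
        b = ConsensusHaplotype(
            name="B",
            region=big,
            positions=pos,
            calls=["G"] * n_diff,
            support=np.full(n_diff, 6),
            ambiguous_positions=[],
        )
        records, L = inter_haplotype_catalog(a, b)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 2700)
        assert lo <= len(records) <= hi
        assert L == region_len


def _scan_oracle(match, max_mismatch):
    n = len(match)
    valid = [
        (a, b)
        for a in range(n)
        for b in range(a + 1, n + 1)
        if (b - a) - sum(match[a:b]) <= max_mismatch
    ]
    return sorted(
        (a, b)
        for a, b in valid
        if not any((c, d) != (a, b) and c <= a and b <= d for c, d in valid)
    )


class TestSharedSegmentScan:
    def test_identical_vectors(self):
        v = ["A"] * 100
        (seg,) = shared_segment_scan(v, v)
        assert (seg.start_index, seg.end_index, seg.n_match, seg.n_total) == (0, 100, 100, 100)

    def test_published_fig_configuration(self):
        ref = ["A"] * 1508
        query = list(ref)
        query[400] = "G"
        query[900] = "G"
        segments = shared_segment_scan(query, ref, max_mismatch=2)
        assert len(segments) == 1
        assert segments[0].n_match == 1506 and segments[0].n_total == 1508

    def test_three_mismatches_split_into_two_maximal_segments(self):
        ref = ["A"] * 200
        query = list(ref)
        for i in (50, 100, 150):
            query[i] = "T"
        segments = shared_segment_scan(query, ref, max_mismatch=2)
        got = sorted((s.start_index, s.end_index) for s in segments)
        match = [q == r for q, r in zip(query, ref)]
        assert got == _scan_oracle(match, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        match = (rng.random(60) > 0.15).tolist()
        query = ["A" if m else "G" for m in match]
        ref = ["A"] * 60
        segments = shared_segment_scan(query, ref, max_mismatch=2)
        got = sorted((s.start_index, s.end_index) for s in segments)
        assert got == _scan_oracle(match, 2)

    def test_second_reference_must_agree(self):
        query = ["A", "A", "A"]
        ref_a = ["A", "A", "A"]
        ref_b = ["A", "G", "A"]
        segments = shared_segment_scan(query, ref_a, ref_b, max_mismatch=0)
        # disagreement with ref_b at index 1 breaks the run in two
        assert sorted((s.start_index, s.end_index) for s in segments) == [(0, 1), (2, 3)]
        assert all(s.n_match == 1 for s in segments)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shared_segment_scan(["A"], ["A", "C"])
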