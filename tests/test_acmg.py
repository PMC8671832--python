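"""Automated dosage-rubric evidence assignment, score and banding."""
import pytest

from tadsv.acmg import (
    AcmgEvidence,
    assign_evidence,
    classify_score,
    final_score,
    score_cnv,
)
from tadsv.annotation import ElementHit
from tadsv.core import (
    Breakpoint,
    CnvDbRecord,
    GeneRecord,
    GenomicInterval,
    StructuralVariant,
)
from tadsv.overlap import BestHitsResult, OverlapHit
from tadsv.regions import ResolvedRegion


def gene(start, end, gene_id="G", biotype="protein_coding", hi=False, ts=False):
    return GeneRecord(
        gene_id, gene_id, GenomicInterval("chr1", start, end), "+", biotype,
        haploinsufficient=hi, triplosensitive=ts,
    )


def hit_for(g, bp_pos=None):
    region = ResolvedRegion(
        GenomicInterval("chr1", 0, 1_000_000), "brTAD", 0,
        Breakpoint("chr1", bp_pos) if bp_pos is not None else None,
    )
    disrupted = bp_pos is not None and g.span.start < bp_pos < g.span.end
    return ElementHit(g, region, disrupted_by_breakpoint=disrupted)


def deletion(start=10_000, end=100_000):
    return StructuralVariant("deletion", span=GenomicInterval("chr1", start, end))


def best_hit_result(query, cls="likely_benign", mutual=100.0):
    rec = CnvDbRecord(query, "loss", cls, 0.001, "clingen", "nsv1")
    return BestHitsResult(
        {"clingen": OverlapHit(query, rec, mutual, mutual, mutual)}, []
    )


class TestAssignEvidence:
    def test_benign_overlap_worked_example(self):
        """Five genes without dosage evidence plus a 100% likely-benign
        best hit resolve to 1A + 3A + benign-overlap = -0.90."""
        sv = deletion(10_000, 100_000)
        genes = [gene(15_000 + i * 15_000, 25_000 + i * 15_000, f"G{i}") for i in range(5)]
        hits = [hit_for(g) for g in genes]
        ev = assign_evidence(sv, hits, best_hit_result(sv.span))
        assert {e.criterion_id: e.points for e in ev} == {
            "1A": 0.0, "benign-overlap": -0.90, "3A": 0.0,
        }
        assert final_score(ev) == -0.90
        assert classify_score(final_score(ev)) == "likely_benign"

    def test_empty_content_scores_1b(self):
        ev = assign_evidence(deletion(), [], None)
        assert {e.criterion_id: e.points for e in ev} == {"1B": -0.60, "3A": 0.0}

    def test_only_nonfunctional_content_scores_1b(self):
        nf = gene(20_000, 30_000, "NF", biotype="non_functional")
        ev = assign_evidence(deletion(), [hit_for(nf)], None)
        assert any(e.criterion_id == "1B" for e in ev)

    def test_contained_haploinsufficient_gene_fires_2a(self):
        hi = gene(20_000, 30_000, "HI", hi=True)
        ev = assign_evidence(deletion(), [hit_for(hi)], None)
        assert {e.criterion_id for e in ev} >= {"1A", "2A"}
        assert final_score(ev) == 1.00
        assert classify_score(1.00) == "pathogenic"

    def test_triplosensitive_gene_fires_2a_for_gains_only(self):
        ts = gene(20_000, 30_000, "TS", ts=True)
        dup = StructuralVariant("duplication", span=GenomicInterval("chr1", 10_000, 100_000))
        ev_gain = assign_evidence(dup, [hit_for(ts)], None)
        assert any(e.criterion_id == "2A" for e in ev_gain)
        ev_loss = assign_evidence(deletion(), [hit_for(ts)], None)
        assert not any(e.criterion_id == "2A" for e in ev_loss)

    def test_2f_containment_in_benign_region_suppresses_benign_overlap(self):
        sv = deletion(10_000, 100_000)
        g = gene(20_000, 30_000)
        benign_region = GenomicInterval("chr1", 0, 200_000)
        ev = assign_evidence(sv, [hit_for(g)], best_hit_result(sv.span), [benign_region])
        ids = {e.criterion_id for e in ev}
        assert "2F" in ids and "benign-overlap" not in ids

    def test_gene_count_bins_loss(self):
        sv = deletion(10_000, 500_000)
        def evidence_for(n):
            genes = [gene(10_000 + i * 900, 10_500 + i * 900, f"G{i}") for i in range(n)]
            ev = assign_evidence(sv, [hit_for(g) for g in genes], None)
            return {e.criterion_id for e in ev}
        assert "3A" in evidence_for(24)
        assert "3B" in evidence_for(25)
        assert "3B" in evidence_for(34)
        assert "3C" in evidence_for(35)

    def test_gene_count_bins_gain(self):
        dup = StructuralVariant("duplication", span=GenomicInterval("chr1", 10_000, 500_000))
        def evidence_for(n):
            genes = [gene(10_000 + i * 900, 10_500 + i * 900, f"G{i}") for i in range(n)]
            ev = assign_evidence(dup, [hit_for(g) for g in genes], None)
            return {e.criterion_id for e in ev}
        assert "3A" in evidence_for(34)
        assert "3B" in evidence_for(35)
        assert "3C" in evidence_for(50)

    def test_balanced_sv_rejected(self):
        t = StructuralVariant(
            "translocation", (Breakpoint("chr1", 1), Breakpoint("chr2", 1))
        )
        with pytest.raises(ValueError):
            assign_evidence(t, [], None)

    def test_mutual_exclusivity_within_sections(self):
        """At most one of 1A/1B, one of 3A/3B/3C; 2F and benign-overlap
        never co-fire."""
        sv = deletion(10_000, 100_000)
        cases = [
            assign_evidence(sv, [], None),
            assign_evidence(sv, [hit_for(gene(20_000, 30_000))], best_hit_result(sv.span)),
            assign_evidence(
                sv, [hit_for(gene(20_000, 30_000))], best_hit_result(sv.span),
                [GenomicInterval("chr1", 0, 200_000)],
            ),
        ]
        for ev in cases:
            ids = [e.criterion_id for e in ev]
            assert sum(i in {"1A", "1B"} for i in ids) == 1
            assert sum(i in {"3A", "3B", "3C"} for i in ids) == 1
            assert not ({"2F", "benign-overlap"} <= set(ids))


class TestScoreAndBands:
    def test_empty_evidence_is_vus(self):
        assert final_score([]) == 0.0
        assert classify_score(0.0) == "vus"

    @pytest.mark.parametrize(
        "score,expected",
        [
            (1.00, "pathogenic"), (0.99, "pathogenic"),
            (0.98, "likely_pathogenic"), (0.90, "likely_pathogenic"),
            (0.89, "vus"), (0.0, "vus"), (-0.89, "vus"),
            (-0.90, "likely_benign"), (-0.98, "likely_benign"),
            (-0.99, "benign"), (-2.0, "benign"),
        ],
    )
    def test_band_edges(self, score, expected):
        assert classify_score(score) == expected

    def test_band_partition_and_monotonicity(self):
        import numpy as np

        order = ["benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic"]
        prev = None
        for s in np.arange(-1.5, 1.5, 0.01):
            cls = classify_score(round(float(s), 2))
            assert cls in order
            if prev is not None:
                assert order.index(cls) >= order.index(prev)
            prev = cls

    def test_manual_evidence_added(self):
        ev = [AcmgEvidence("1A", 0.0)]
        assert final_score(ev, manual={"4A": 0.45}) == 0.45

    def test_out_of_range_points_rejected(self):
        with pytest.raises(ValueError):
            AcmgEvidence("2A", 0.5)


def test_fixture_worked_example_end_to_end(resources, manifest):
    """The planted deletion reproduces the rubric outcome recorded in the
    fixture manifest via the full pipeline path."""
    from tadsv.pipeline import interpret_sv

    truth = manifest["planted"]["ck_deletion"]
    sv = StructuralVariant(
        "deletion",
        span=GenomicInterval(truth["chrom"], truth["start"], truth["end"]),
        sv_id="CK",
    )
    interp = interpret_sv(sv, resources)
    res = interp.acmg_result
    assert res is not None
    assert {e.criterion_id: e.points for e in res.evidence} == truth["acmg_evidence"]
    assert res.final_score == truth["acmg_score"] == -0.90
    assert res.acmg_class == truth["acmg_class"] == "likely_benign"
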