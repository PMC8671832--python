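"""End-to-end interpretation: resolve regions, annotate, score, classify,
and emit report rows.

This is the glue the CLI (and batch mode) drives; each step is a thin call
into the dedicated module so the pieces stay independently testable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import acmg
from .annotation import ElementHit, collect_elements, ucsc_session_url
from .classify import ClassifierConfig, SvClassification, classify_balanced
from .core import (
    CnvDbRecord,
    CytobandRecord,
    GeneRecord,
    GenomicInterval,
    LoopRecord,
    RegClusterRecord,
    StructuralVariant,
)
from .overlap import BestHitsResult, best_hits, group_by_db
from .phenosim import OntologyGraph, SimilarityResult
from .regions import ResolvedRegion, TADMap, regions_for_sv
from .report import BandLookup, format_iscn, sv_length_label


@dataclass
class Resources:
    """Loaded annotation universe shared by all SVs in a run."""

    tads: TADMap
    genes: Sequence[GeneRecord] = ()
    loops: Sequence[LoopRecord] = ()
    clusters: Sequence[RegClusterRecord] = ()
    cytobands: Sequence[CytobandRecord] = ()
    cnv_dbs: Mapping[str, Sequence[CnvDbRecord]] = field(default_factory=dict)
    ontology: Optional[OntologyGraph] = None


@dataclass
class Interpretation:
    sv: StructuralVariant
    regions: list[ResolvedRegion]
    element_hits: list[ElementHit]
    similarity: dict[str, SimilarityResult]
    overlap: Optional[BestHitsResult]
    acmg_result: Optional[acmg.AcmgResult]
    classification: Optional[SvClassification]

    @property
    def category(self) -> str:
        if self.acmg_result is not None:
            return self.acmg_result.acmg_class
        if self.classification is not None:
            return self.classification.category
        return ""  # region mode: annotation only, no classification


def interpret_sv(
    sv: StructuralVariant,
    resources: Resources,
    phenotype: Sequence[str] = (),
    flank_k: int = 0,
    overlap_threshold: float = 70.0,
    perm_n: int = 100,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    manual_evidence: Mapping[str, float] | None = None,
) -> Interpretation:
    """Interpret one SV against the loaded annotation universe.

    ``phenotype`` is the patient's ontology term list; when given,
    similarity scores are computed per disorder linked to any gene in the
    analysed regions.  CNVs are routed to the overlap search + ACMG
    rubric, balanced SVs (and insertions) to the rule-based classifier;
    region mode only annotates.
    """
    regions = regions_for_sv(sv, resources.tads, k=flank_k)
    element_hits: list[ElementHit] = []
    for region in regions:
        element_hits.extend(
            collect_elements(
                region, resources.genes, resources.clusters, resources.loops
            )
        )

    similarity: dict[str, SimilarityResult] = {}
    if phenotype and resources.ontology is not None:
        onto = resources.ontology
        for h in element_hits:
            g = h.element
            if not isinstance(g, GeneRecord):
                continue
            for link in g.disorders:
                disease = onto.diseases.get(link.disease_id)
                if disease is None or link.disease_id in similarity:
                    continue
                similarity[link.disease_id] = onto.score_disease(
                    phenotype, disease, n=perm_n, seed=seed
                )

    overlap_result: Optional[BestHitsResult] = None
    acmg_result: Optional[acmg.AcmgResult] = None
    classification: Optional[SvClassification] = None
    if sv.is_cnv:
        assert sv.span is not None and sv.cnv_type is not None
        overlap_result = best_hits(
            sv.span, sv.cnv_type, resources.cnv_dbs, threshold=overlap_threshold
        )
        acmg_result = acmg.score_cnv(
            sv, element_hits, overlap_result, manual=manual_evidence
        )
    elif sv.is_balanced:
        gene_similarity = _best_similarity_per_gene(element_hits, similarity)
        classification = classify_balanced(sv, element_hits, gene_similarity, config)

    return Interpretation(
        sv, regions, element_hits, similarity, overlap_result, acmg_result,
        classification,
    )


def _best_similarity_per_gene(
    element_hits: Sequence[ElementHit],
    similarity: Mapping[str, SimilarityResult],
) -> dict[str, SimilarityResult]:
    """Map gene_id -> its best-supported disorder similarity (highest
    PhenSSc)."""
    out: dict[str, SimilarityResult] = {}
    for h in element_hits:
        g = h.element
        if not isinstance(g, GeneRecord):
            continue
        for link in g.disorders:
            sim = similarity.get(link.disease_id)
            if sim is None:
                continue
            cur = out.get(g.gene_id)
            if cur is None or sim.phenssc > cur.phenssc:
                out[g.gene_id] = sim
    return out


def report_rows(
    interp: Interpretation, resources: Resources
) -> list[dict[str, object]]:
    """Flatten an interpretation into fixed-schema report rows, one per
    (region, element); regions without elements still yield one row."""
    sv = interp.sv
    lookup = BandLookup(resources.cytobands) if resources.cytobands else None
    iscn = format_iscn(sv, lookup, sv.genome_build) if lookup else ""
    length = sv_length_label(sv.span) if sv.span is not None else ""
    best_hit = _flat_best_hit(interp.overlap)
    acmg_cols = _flat_acmg(interp.acmg_result)
    rows: list[dict[str, object]] = []
    hits_by_region: dict[int, list[ElementHit]] = {}
    for h in interp.element_hits:
        hits_by_region.setdefault(id(h.region), []).append(h)
    for region in interp.regions:
        url = ucsc_session_url(region, sv.genome_build)
        base = {
            "sv_id": sv.sv_id,
            "iscn": iscn,
            "sv_length": length,
            "region_kind": region.kind,
            "region_offset": region.offset,
            "region_interval": (
                f"{region.interval.chrom}:"
                f"{region.interval.display_start}-{region.interval.display_end}"
            ),
            "category": interp.category,
            "ucsc_url": url,
            **best_hit,
            **acmg_cols,
        }
        region_hits = hits_by_region.get(id(region), [])
        if not region_hits:
            rows.append(dict(base))
            continue
        for h in region_hits:
            g = h.element
            row = dict(base)
            if isinstance(g, GeneRecord):
                sim = _gene_best_sim(g, interp.similarity)
                row.update(
                    element_id=g.gene_id,
                    element_symbol=g.symbol,
                    element_biotype=g.biotype,
                    pli="" if g.pli is None else g.pli,
                    oe_lof="" if g.oe_lof is None else g.oe_lof,
                    haploinsufficient=g.haploinsufficient,
                    triplosensitive=g.triplosensitive,
                    disrupted_by_breakpoint=h.disrupted_by_breakpoint,
                    loops_disrupted=h.loops_disrupted,
                    loops_total=h.loops_total,
                    cluster_disrupted=h.cluster_disrupted,
                    disorders=";".join(
                        f"{d.disease_id}:{d.inheritance}" for d in g.disorders
                    ),
                )
                if sim is not None:
                    row.update(
                        phenssc=round(sim.phenssc, 4),
                        maxssc=round(sim.maxssc, 4),
                        p_value=sim.p_value,
                    )
            rows.append(row)
    return rows


def _gene_best_sim(
    gene: GeneRecord, similarity: Mapping[str, SimilarityResult]
) -> Optional[SimilarityResult]:
    best = None
    for link in gene.disorders:
        sim = similarity.get(link.disease_id)
        if sim is not None and (best is None or sim.phenssc > best.phenssc):
            best = sim
    return best


def _flat_best_hit(result: Optional[BestHitsResult]) -> dict[str, object]:
    if result is None or not result.best_by_db:
        return {}
    db, hit = max(
        result.best_by_db.items(), key=lambda kv: (kv[1].mutual_overlap, kv[0])
    )
    return {
        "best_hit_db": db,
        "best_hit_id": hit.record.record_id,
        "best_hit_classification": hit.record.classification,
        "best_hit_mutual_overlap": round(hit.mutual_overlap, 2),
        "best_hit_frequency": (
            "" if hit.record.frequency is None else hit.record.frequency
        ),
    }


def _flat_acmg(result: Optional[acmg.AcmgResult]) -> dict[str, object]:
    if result is None:
        return {}
    return {
        "acmg_evidence": ";".join(
            f"{e.criterion_id}={e.points:+.2f}" for e in result.evidence
        ),
        "acmg_score": f"{result.final_score:.2f}",
        "acmg_class": result.acmg_class,
    }


def overlap_detail_rows(
    interp: Interpretation,
) -> list[dict[str, object]]:
    if interp.overlap is None:
        return []
    return [
        {
            "query_id": interp.sv.sv_id,
            "source_db": h.record.source_db,
            "record_id": h.record.record_id,
            "classification": h.record.classification,
            "frequency": "" if h.record.frequency is None else h.record.frequency,
            "mutual_overlap": round(h.mutual_overlap, 2),
            "query_coverage": round(h.query_coverage, 2),
            "record_coverage": round(h.record_coverage, 2),
        }
        for h in interp.overlap.all_hits
    ]
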