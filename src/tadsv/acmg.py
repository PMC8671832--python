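"""Automated ACMG/ClinGen CNV evidence scoring.

Only the machine-determinable criteria are assigned automatically: the
content section (1A/1B), established dosage-sensitive regions or genes
(2A), complete containment in an established benign region (2F and the
curated benign-overlap analogue), and the gene-count section (3A-3C).
Literature, de novo and inheritance criteria cannot be derived from
annotation files and enter as manual adjustments added to the score.

Scores are reported in hundredths; the final score is the plain sum of
evidence points, banded into the five-tier classification:

    >=  0.99  pathogenic
    0.90-0.98 likely pathogenic
   -0.89-0.89 VUS
   -0.98- -0.90 likely benign
    <= -0.99  benign
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import ElementHit
from .core import GeneRecord, GenomicInterval, StructuralVariant, CnvDbRecord
from .overlap import BestHitsResult

#: allowed point range per automated criterion
RUBRIC_RANGES: dict[str, tuple[float, float]] = {
    "1A": (0.0, 0.0),
    "1B": (-0.60, -0.60),
    "2A": (1.00, 1.00),
    "2F": (-1.00, -1.00),
    "benign-overlap": (-0.90, -0.90),
    "3A": (0.0, 0.0),
    "3B": (0.45, 0.45),
    "3C": (0.90, 0.90),
    "manual": (-1.00, 1.00),
}

#: protein-coding gene-count bin edges (lower bound of 3B, of 3C)
LOSS_GENE_BINS = (25, 35)
GAIN_GENE_BINS = (35, 50)


@dataclass(frozen=True)
class AcmgEvidence:
    criterion_id: str
    points: float
    rationale: str = ""

    def __post_init__(self) -> None:
        key = self.criterion_id if self.criterion_id in RUBRIC_RANGES else "manual"
        lo, hi = RUBRIC_RANGES[key]
        if not lo <= self.points <= hi:
            raise ValueError(
                f"criterion {self.criterion_id}: points {self.points} outside [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class AcmgResult:
    evidence: tuple[AcmgEvidence, ...]
    final_score: float
    acmg_class: str


def assign_evidence(
    cnv: StructuralVariant,
    element_hits: Sequence[ElementHit],
    hits: Optional[BestHitsResult] = None,
    benign_regions: Sequence[GenomicInterval] = (),
) -> list[AcmgEvidence]:
    """Deterministic evidence assignment for a deletion or duplication.

    ``element_hits`` must cover the CNV span (breakpoint TADs plus
    remaining region); ``hits`` is the curated-database overlap result;
    ``benign_regions`` are established benign regions for criterion 2F.
    """
    if not cnv.is_cnv:
        raise ValueError("ACMG scoring applies to deletions/duplications only")
    assert cnv.span is not None
    span = cnv.span
    evidence: list[AcmgEvidence] = []

    genes_in_span = _genes_overlapping(element_hits, span)

    # Section 1: CNV content (protein-coding or functional elements)
    content = [g for g in genes_in_span if g.biotype != "non_functional"]
    if content:
        evidence.append(AcmgEvidence("1A", 0.0, f"contains {len(content)} gene(s)/element(s)"))
    else:
        evidence.append(AcmgEvidence("1B", -0.60, "contains no protein-coding or functional elements"))

    # Section 2: established dosage-sensitive / benign regions
    dosage_flag = (
        (lambda g: g.haploinsufficient)
        if cnv.cnv_type == "loss"
        else (lambda g: g.triplosensitive)
    )
    dosage_hit = None
    for g in genes_in_span:
        if not dosage_flag(g):
            continue
        contained = span.contains(g.span)
        disrupted = any(
            h.disrupted_by_breakpoint
            for h in element_hits
            if isinstance(h.element, GeneRecord) and h.element.gene_id == g.gene_id
        )
        if contained or disrupted:
            dosage_hit = g
            break
    if dosage_hit is not None:
        label = "haploinsufficient" if cnv.cnv_type == "loss" else "triplosensitive"
        evidence.append(
            AcmgEvidence("2A", 1.00, f"established {label} gene {dosage_hit.symbol}")
        )

    in_benign_region = any(region.contains(span) for region in benign_regions)
    if in_benign_region:
        evidence.append(
            AcmgEvidence("2F", -1.00, "completely contained within an established benign region")
        )
    elif hits is not None:
        for db, hit in sorted(hits.best_by_db.items()):
            if (
                hit.record.classification in {"benign", "likely_benign"}
                and hit.mutual_overlap >= 100.0
            ):
                evidence.append(
                    AcmgEvidence(
                        "benign-overlap",
                        -0.90,
                        f"100% mutual overlap with {hit.record.classification} "
                        f"{db} record {hit.record.record_id}",
                    )
                )
                break

    # Section 3: protein-coding gene count
    n_coding = sum(1 for g in genes_in_span if g.biotype == "protein_coding")
    b3, c3 = LOSS_GENE_BINS if cnv.cnv_type == "loss" else GAIN_GENE_BINS
    if n_coding >= c3:
        evidence.append(AcmgEvidence("3C", 0.90, f"{n_coding} protein-coding genes"))
    elif n_coding >= b3:
        evidence.append(AcmgEvidence("3B", 0.45, f"{n_coding} protein-coding genes"))
    else:
        evidence.append(AcmgEvidence("3A", 0.0, f"{n_coding} protein-coding genes"))
    return evidence


def _genes_overlapping(
    element_hits: Sequence[ElementHit], span: GenomicInterval
) -> list[GeneRecord]:
    seen: dict[str, GeneRecord] = {}
    for h in element_hits:
        g = h.element
        if isinstance(g, GeneRecord) and g.span.overlap_bp(span) > 0:
            seen.setdefault(g.gene_id, g)
    return list(seen.values())


def final_score(
    evidence: Iterable[AcmgEvidence],
    manual: Mapping[str, float] | None = None,
) -> float:
    """Sum of evidence points (plus manual adjustments), in hundredths."""
    total = sum(e.points for e in evidence)
    if manual:
        total += sum(manual.values())
    return round(total, 2)


def classify_score(score: float) -> str:
    """Map a final score to its five-tier class (total, monotone banding)."""
    if score >= 0.99:
        return "pathogenic"
    if score >= 0.90:
        return "likely_pathogenic"
    if score > -0.90:
        return "vus"
    if score > -0.99:
        return "likely_benign"
    return "benign"


def score_cnv(
    cnv: StructuralVariant,
    element_hits: Sequence[ElementHit],
    hits: Optional[BestHitsResult] = None,
    benign_regions: Sequence[GenomicInterval] = (),
    manual: Mapping[str, float] | None = None,
) -> AcmgResult:
    """Convenience wrapper: evidence, summed score and class in one call."""
    ev = assign_evidence(cnv, element_hits, hits, benign_regions)
    if manual:
        for cid, pts in sorted(manual.items()):
            ev.append(AcmgEvidence(cid, pts, "manual adjustment"))
    score = final_score(ev)
    return AcmgResult(tuple(ev), score, classify_score(score))
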