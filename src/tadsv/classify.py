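"""Rule engines for SV interpretation.

Three independent pieces:

* a precedence-ordered classifier for balanced SVs and insertions
  (pathogenic > likely pathogenic > likely benign > benign, everything else
  VUS), combining gene disruption, constraint, disorder inheritance and a
  position-effect arm;
* prefilters for sequencing-derived SV triage (size, population frequency,
  LoF-constraint / AD-disorder gene involvement);
* the three-evaluator consensus merge (majority, else median on the
  ordered five-level scale).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .annotation import ElementHit
from .core import (
    CLASSIFICATIONS,
    CnvDbRecord,
    GeneRecord,
    GenomicInterval,
    StructuralVariant,
)
from .overlap import best_hits as _best_hits, group_by_db
from .phenosim import SimilarityResult

log = logging.getLogger(__name__)

CATEGORY_ORDER = {c: i for i, c in enumerate(CLASSIFICATIONS)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds for the balanced-SV rule engine."""

    phen_ratio: float = 0.5      # minimum PhenSSc/MaxSSc for phenotype support
    alpha: float = 0.05          # maximum permutation p for phenotype support
    force_phenotype_overlap: bool = False  # expert override of the phenotype gate
    min_sv_size: int = 1000      # bp, sequencing-triage size floor
    max_frequency: float = 0.01  # population-frequency ceiling for triage
    max_oe_lof: float = 0.35     # LoF constraint ceiling flagging sensitive genes


@dataclass(frozen=True)
class SvClassification:
    sv_id: str
    category: str
    triggered_rules: tuple[str, ...]
    phenotype_support: Optional[SimilarityResult] = None


def phenotype_overlap_flag(
    similarity: Optional[SimilarityResult],
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """Significant phenotype overlap: PhenSSc close to MaxSSc (ratio >=
    ``phen_ratio``) with a small permutation p (<= ``alpha``)."""
    if similarity is None:
        return False
    if similarity.maxssc <= 0:
        log.warning("MaxSSc is 0; phenotype overlap flag set to False")
        return False
    return (
        similarity.phenssc / similarity.maxssc >= config.phen_ratio
        and similarity.p_value <= config.alpha
    )


def _gene_hits(element_hits: Iterable[ElementHit]) -> list[ElementHit]:
    return [h for h in element_hits if isinstance(h.element, GeneRecord)]


def _affected(h: ElementHit, sv: StructuralVariant) -> bool:
    """A gene is 'affected or encompassed' when it is disrupted by a
    breakpoint or (for spanned SVs) lies fully inside the span."""
    if h.disrupted_by_breakpoint:
        return True
    if sv.span is not None and isinstance(h.element, GeneRecord):
        return sv.span.contains(h.element.span)
    return False


def classify_balanced(
    sv: StructuralVariant,
    element_hits: Sequence[ElementHit],
    similarity: Mapping[str, SimilarityResult] | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> SvClassification:
    """Classify a balanced SV or insertion on the five-level scale.

    The first matching rule in precedence order wins; a variant matching
    several arms takes the most pathogenic one (clinical conservatism).
    The position-effect arm requires a candidate gene in a breakpoint or
    flanking TAD whose long-range regulatory interactions are predicted to
    be impacted (severed cluster or >= 1 disrupted loop) in a subject with
    significant phenotype overlap for that gene's disorder.
    """
    if sv.is_cnv:
        raise ValueError("CNVs are scored by the ACMG rubric, not this classifier")
    similarity = similarity or {}
    genes = _gene_hits(element_hits)
    affected = [h for h in genes if _affected(h, sv)]
    rules: list[str] = []
    support: Optional[SimilarityResult] = None

    def has_inheritance(h: ElementHit, mode: str) -> bool:
        return any(d.inheritance == mode for d in h.element.disorders)

    # Pathogenic: affected/encompassed gene with a dominant disorder
    for h in affected:
        if has_inheritance(h, "AD"):
            return SvClassification(
                sv.sv_id, "pathogenic",
                (f"affected gene {h.element.symbol} linked to AD disorder",),
                similarity.get(h.element.gene_id),
            )

    # Likely pathogenic, arm 1: constrained gene without disease association
    for h in affected:
        g = h.element
        if g.pli is not None and g.pli >= 0.9 and not g.disorders:
            return SvClassification(
                sv.sv_id, "likely_pathogenic",
                (f"affected gene {g.symbol} with pLI {g.pli:.2f} and no disorder link",),
                None,
            )

    # Likely pathogenic, arm 2: position effect on a nearby AD candidate
    for h in genes:
        g = h.element
        if h.region.kind not in {"brTAD", "flankTAD"}:
            continue
        if not has_inheritance(h, "AD"):
            continue
        if not (h.cluster_disrupted or h.loops_disrupted >= 1):
            continue
        sim = similarity.get(g.gene_id)
        if config.force_phenotype_overlap or phenotype_overlap_flag(sim, config):
            return SvClassification(
                sv.sv_id, "likely_pathogenic",
                (f"position effect on AD candidate {g.symbol} "
                 f"(cluster_disrupted={h.cluster_disrupted}, "
                 f"loops_disrupted={h.loops_disrupted})",),
                sim,
            )

    # Likely benign: affected genes only associated with AR disorders
    if affected and all(
        h.element.disorders
        and all(d.inheritance == "AR" for d in h.element.disorders)
        for h in affected
    ):
        return SvClassification(
            sv.sv_id, "likely_benign",
            ("affected genes only associated with AR disorders",),
            None,
        )

    # Benign: no genes affected and no disorder-linked element in the
    # disrupted TADs
    brtad_hits = [h for h in genes if h.region.kind == "brTAD"]
    if not affected and not any(h.element.disorders for h in brtad_hits):
        return SvClassification(
            sv.sv_id, "benign",
            ("no affected genes; no disorder-linked elements in brTADs",),
            None,
        )

    return SvClassification(sv.sv_id, "vus", ("no classification rule matched",), None)


@dataclass(frozen=True)
class SvCandidate:
    """A sequencing-derived SV call entering triage (pre-interpretation, so
    size limits are not yet enforced)."""

    sv_id: str
    span: GenomicInterval
    cnv_type: str = "loss"


def prefilter_sequencing_svs(
    candidates: Sequence[SvCandidate],
    dbs: Mapping[str, Sequence[CnvDbRecord]],
    genes: Sequence[GeneRecord],
    config: ClassifierConfig = ClassifierConfig(),
    overlap_threshold: float = 70.0,
) -> list[SvCandidate]:
    """Triage sequencing SV calls for clinical evaluation.

    Keep a call iff its span exceeds the size floor, it is novel or its
    best database hit is rarer than the frequency ceiling, and it touches
    a LoF-sensitive gene (oe < 0.35) or a gene linked to an AD disorder.
    """
    kept = []
    for c in candidates:
        if c.span.length <= config.min_sv_size:
            continue
        result = _best_hits(c.span, c.cnv_type, dbs, threshold=overlap_threshold)
        freqs = [
            h.record.frequency
            for h in result.best_by_db.values()
            if h.record.frequency is not None
        ]
        if freqs and max(freqs) >= config.max_frequency:
            continue
        touching = [g for g in genes if g.span.overlap_bp(c.span) > 0]
        sensitive = any(
            g.oe_lof is not None and g.oe_lof < config.max_oe_lof for g in touching
        )
        ad_linked = any(
            any(d.inheritance == "AD" for d in g.disorders) for g in touching
        )
        if sensitive or ad_linked:
            kept.append(c)
    return kept


def consensus_classification(calls: Sequence[str]) -> str:
    """Merge exactly three evaluator calls: a category shared by at least
    two wins; otherwise the median on the ordered five-level scale."""
    if len(calls) != 3:
        raise ValueError(f"consensus requires exactly 3 calls, got {len(calls)}")
    for c in calls:
        if c not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {c!r}")
    for c in set(calls):
        if calls.count(c) >= 2:
            return c
    return sorted(calls, key=CATEGORY_ORDER.__getitem__)[1]
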