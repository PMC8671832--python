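"""Element retrieval per resolved region, with disruption flags.

Two retrieval rules apply.  From breakpoint-containing TADs every
functional and non-functional element is collected; from the remaining
region of a CNV (and from explicit genomic regions) only protein-coding
genes, lincRNAs, lncRNAs and elements with a tissue expression pattern are
kept.  Disruption flags mark genes split by a breakpoint, chromatin loops
whose anchors end up on opposite sides of a breakpoint, and regulatory
clusters severed between an enhancer and its target.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .core import (
    Breakpoint,
    GeneRecord,
    GenomicInterval,
    LoopRecord,
    RegClusterRecord,
    REMAINING_REGION_BIOTYPES,
)
from .regions import ResolvedRegion

Element = Union[GeneRecord, RegClusterRecord, LoopRecord]


@dataclass(frozen=True)
class ElementHit:
    element: Element
    region: ResolvedRegion
    disrupted_by_breakpoint: bool = False
    loops_total: int = 0
    loops_disrupted: int = 0
    cluster_disrupted: bool = False
    intergenic_breakpoint: bool = False

    def __post_init__(self) -> None:
        if self.loops_disrupted > self.loops_total:
            raise ValueError("loops_disrupted cannot exceed loops_total")


def flag_gene_disruption(bp: Breakpoint, gene: GeneRecord) -> bool:
    """True iff the breakpoint lies strictly inside the gene body.

    Breakpoints at the exact gene boundaries count as flanking, not
    disrupting.
    """
    if bp.chrom != gene.span.chrom:
        return False
    return gene.span.start < bp.pos < gene.span.end


def count_disrupted_loops(
    bp: Breakpoint, gene: GeneRecord, loops: Iterable[LoopRecord]
) -> tuple[int, int]:
    """(disrupted, total) chromatin loops for a gene.

    ``total`` counts loops with either anchor overlapping the gene span;
    a loop is disrupted when the breakpoint falls strictly between its
    anchors (anchor-internal breaks are not counted).
    """
    total = 0
    disrupted = 0
    for lp in loops:
        if lp.anchor_a.chrom != gene.span.chrom:
            continue
        if not (
            lp.anchor_a.overlap_bp(gene.span) > 0
            or lp.anchor_b.overlap_bp(gene.span) > 0
        ):
            continue
        total += 1
        if bp.chrom == lp.anchor_a.chrom and lp.anchor_a.end <= bp.pos < lp.anchor_b.start:
            disrupted += 1
    return disrupted, total


def flag_cluster_disruption(bp: Breakpoint, cluster: RegClusterRecord) -> bool:
    """True iff the breakpoint severs the cluster: it falls within the
    cluster hull and at least one element lies entirely on each side."""
    if bp.chrom != cluster.chrom:
        return False
    hull = cluster.hull
    if not (hull.start <= bp.pos < hull.end):
        return False
    left = any(e.end <= bp.pos for e in cluster.elements)
    right = any(e.start > bp.pos for e in cluster.elements)
    return left and right


def _passes_remaining_filter(gene: GeneRecord) -> bool:
    return gene.biotype in REMAINING_REGION_BIOTYPES or gene.has_expression_pattern


def collect_elements(
    region: ResolvedRegion,
    genes: Sequence[GeneRecord],
    clusters: Sequence[RegClusterRecord] = (),
    loops: Sequence[LoopRecord] = (),
) -> list[ElementHit]:
    """Collect elements overlapping a resolved region and compute flags.

    Breakpoint-style retrieval (brTAD and flanking TADs) keeps every
    overlapping element; remaining/explicit regions apply the
    expression-pattern filter.  Per-gene loop counts and cluster flags are
    computed against the region's source breakpoint when there is one.
    """
    bp = region.source_breakpoint
    breakpoint_style = region.kind in {"brTAD", "flankTAD"}
    hits: list[ElementHit] = []
    gene_hits = [g for g in genes if g.span.overlap_bp(region.interval) > 0]
    any_gene_at_bp = bp is not None and any(
        flag_gene_disruption(bp, g) for g in gene_hits
    )
    for g in gene_hits:
        if not breakpoint_style and not _passes_remaining_filter(g):
            continue
        disrupted = bp is not None and flag_gene_disruption(bp, g)
        if bp is not None:
            loops_disrupted, loops_total = count_disrupted_loops(bp, g, loops)
        else:
            loops_disrupted = loops_total = 0
        cluster = next((c for c in clusters if c.target_gene == g.gene_id), None)
        cluster_disrupted = (
            bp is not None
            and cluster is not None
            and flag_cluster_disruption(bp, cluster)
        )
        hits.append(
            ElementHit(
                element=g,
                region=region,
                disrupted_by_breakpoint=disrupted,
                loops_total=loops_total,
                loops_disrupted=loops_disrupted,
                cluster_disrupted=cluster_disrupted,
                intergenic_breakpoint=bp is not None and not any_gene_at_bp,
            )
        )
    return hits


def ucsc_session_url(region: ResolvedRegion, build: str) -> str:
    """Deterministic UCSC browser URL for a resolved region (1-based)."""
    if not build:
        raise ValueError("genome build label must be non-empty")
    iv = region.interval
    return (
        "https://genome.ucsc.edu/cgi-bin/hgTracks"
        f"?db={build}&position={iv.chrom}:{iv.display_start}-{iv.display_end}"
    )
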