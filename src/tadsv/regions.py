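"""Resolve the genomic regions to analyse for a structural variant.

The unit of analysis is the TAD containing a breakpoint (the brTAD), with
up to five flanking TADs on each side (TAD-5 .. TAD+5, numbered in
coordinate order).  Breakpoints falling in an inter-TAD gap resolve to the
gap interval itself, flagged as a boundary/gap, because boundary regions
restrict regulatory interactions and deserve explicit surfacing.  For
chromosomes without called TADs (chrY in practice), a fixed-size sliding
window tiling — the per-tissue average TAD size — stands in for the TAD
grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .core import (
    Breakpoint,
    GenomicInterval,
    StructuralVariant,
    TadRecord,
    ValidationError,
)

MAX_FLANK = 5


class ResolutionError(KeyError):
    """Breakpoint chromosome absent from the TAD map and no fallback set."""


@dataclass(frozen=True)
class ResolvedRegion:
    interval: GenomicInterval
    kind: str  # brTAD | flankTAD | remaining | explicit
    offset: int = 0
    source_breakpoint: Optional[Breakpoint] = None
    annotation: str = ""  # e.g. "boundary/gap", "average-size window"

    def __post_init__(self) -> None:
        if abs(self.offset) > MAX_FLANK:
            raise ValidationError(f"flank offset {self.offset} outside [-5, 5]")
        if (self.offset == 0) != (self.kind in {"brTAD", "remaining", "explicit"}):
            raise ValidationError("offset 0 is reserved for non-flank regions")


class TADMap:
    """Per-chromosome ordered, non-overlapping TAD intervals for one tissue.

    Provides O(log n) breakpoint containment via an interval tree plus
    ordinal access for flank arithmetic.  ``avg_fallback_size`` enables the
    average-TAD-size window fallback for chromosomes with no called TADs.
    """

    def __init__(self, tads: list[TadRecord], avg_fallback_size: Optional[int] = None):
        self.tissue = tads[0].tissue if tads else ""
        self.avg_fallback_size = avg_fallback_size
        self._by_chrom: dict[str, list[TadRecord]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in sorted(tads, key=lambda t: (t.interval.chrom, t.interval.start)):
            self._by_chrom.setdefault(t.interval.chrom, []).append(t)
        for chrom, recs in self._by_chrom.items():
            indices = [r.index for r in recs]
            if indices != list(range(len(recs))):
                raise ValidationError(
                    f"TAD indices on {chrom} are not consecutive from 0: {indices}"
                )
            tree = IntervalTree()
            for r in recs:
                tree[r.interval.start:r.interval.end] = r
            self._trees[chrom] = tree

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def tads_on(self, chrom: str) -> list[TadRecord]:
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


def chry_fallback_window(bp: Breakpoint, avg_size: int) -> ResolvedRegion:
    """Average-TAD-size window standing in for a brTAD on chromosomes
    without called TADs.  Windows tile the chromosome from 0 in steps of
    ``avg_size``."""
    if avg_size <= 0:
        raise ValueError(f"avg_size must be positive, got {avg_size}")
    k = bp.pos // avg_size
    iv = GenomicInterval(bp.chrom, k * avg_size, (k + 1) * avg_size)
    return ResolvedRegion(iv, "brTAD", 0, bp, "average-size window")


def _fallback_flanks(bp: Breakpoint, avg_size: int, k: int) -> list[ResolvedRegion]:
    base = (bp.pos // avg_size) * avg_size
    out = []
    for off in range(-k, k + 1):
        if off == 0:
            continue
        start = base + off * avg_size
        if start < 0:
            continue
        out.append(
            ResolvedRegion(
                GenomicInterval(bp.chrom, start, start + avg_size),
                "flankTAD",
                off,
                bp,
                "average-size window",
            )
        )
    return out


def resolve_brtad(bp: Breakpoint, tads: TADMap) -> ResolvedRegion:
    """Return the TAD containing the breakpoint (half-open containment).

    A breakpoint in an inter-TAD gap (before the first TAD, between two
    TADs, or past the last) returns the gap interval flagged
    ``boundary/gap``; past-the-end gaps are clipped to one base beyond the
    breakpoint since the chromosome length is unknown.
    """
    recs = tads.tads_on(bp.chrom)
    if not recs:
        if tads.avg_fallback_size:
            return chry_fallback_window(bp, tads.avg_fallback_size)
        raise ResolutionError(
            f"chromosome {bp.chrom} absent from TAD map and no fallback configured"
        )
    hits = tads._trees[bp.chrom][bp.pos]
    if hits:
        rec = next(iter(hits)).data
        return ResolvedRegion(rec.interval, "brTAD", 0, bp)
    # gap: find the flanking TADs by coordinate
    before = [r for r in recs if r.interval.end <= bp.pos]
    after = [r for r in recs if r.interval.start > bp.pos]
    gap_start = before[-1].interval.end if before else 0
    gap_end = after[0].interval.start if after else bp.pos + 1
    return ResolvedRegion(
        GenomicInterval(bp.chrom, gap_start, gap_end), "brTAD", 0, bp, "boundary/gap"
    )


def flanking_tads(bp: Breakpoint, tads: TADMap, k: int) -> list[ResolvedRegion]:
    """Up to k TADs on each side of the brTAD, in coordinate order.

    Offsets run -k..-1 (lower coordinates) and +1..+k (higher), truncated
    at chromosome ends.  For a gap brTAD, offset -1 is the TAD ending at
    the gap and +1 the TAD starting after it.
    """
    if not 0 <= k <= MAX_FLANK:
        raise ValueError(f"flank count k must be in 0..{MAX_FLANK}, got {k}")
    if k == 0:
        return []
    recs = tads.tads_on(bp.chrom)
    if not recs:
        if tads.avg_fallback_size:
            return _fallback_flanks(bp, tads.avg_fallback_size, k)
        raise ResolutionError(
            f"chromosome {bp.chrom} absent from TAD map and no fallback configured"
        )
    br = resolve_brtad(bp, tads)
    # ordinal position: for a real brTAD its index; for a gap, the slot
    # between the two neighbouring indices
    out = []
    if br.annotation == "boundary/gap":
        left_idx = max(
            (r.index for r in recs if r.interval.end <= bp.pos), default=-1
        )
        lo_range = range(left_idx, left_idx - k, -1)
        hi_start = left_idx + 1
    else:
        center = next(r.index for r in recs if r.interval == br.interval)
        lo_range = range(center - 1, center - k - 1, -1)
        hi_start = center + 1
    for off, idx in enumerate(lo_range, start=1):
        if idx < 0:
            break
        out.append(ResolvedRegion(recs[idx].interval, "flankTAD", -off, bp))
    for off, idx in enumerate(range(hi_start, hi_start + k), start=1):
        if idx >= len(recs):
            break
        out.append(ResolvedRegion(recs[idx].interval, "flankTAD", +off, bp))
    out.sort(key=lambda r: r.offset)
    return out


def regions_for_sv(sv: StructuralVariant, tads: TADMap, k: int = 0) -> list[ResolvedRegion]:
    """All regions to annotate for an SV.

    Balanced SVs and insertions: brTAD + flanks per breakpoint.  CNVs:
    brTADs of both span ends with flanks, plus the interior of the span
    (span minus the two brTADs) as a ``remaining`` region.  Region mode:
    the explicit span, unchanged.
    """
    if sv.sv_type == "region":
        assert sv.span is not None
        return [ResolvedRegion(sv.span, "explicit", 0, None)]
    regions: list[ResolvedRegion] = []
    for bp in sv.effective_breakpoints():
        br = resolve_brtad(bp, tads)
        regions.append(br)
        regions.extend(flanking_tads(bp, tads, k))
    if sv.is_cnv:
        assert sv.span is not None
        brs = [r for r in regions if r.kind == "brTAD"]
        interior_start = max(sv.span.start, min(r.interval.end for r in brs))
        interior_end = min(sv.span.end, max(r.interval.start for r in brs))
        if interior_start < interior_end:
            regions.append(
                ResolvedRegion(
                    GenomicInterval(sv.span.chrom, interior_start, interior_end),
                    "remaining",
                    0,
                    None,
                )
            )
    return regions
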