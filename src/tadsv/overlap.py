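"""Reciprocal ("mutual") overlap search of a query CNV against curated
CNV database snapshots.

The mutual overlap of two intervals is the smaller of the two coverage
percentages, so requiring mutual >= t is the same as requiring both
coverages >= t (the classic reciprocal-overlap rule).  The search returns
the best hit per database — the candidate maximising mutual overlap — plus
a detailed table of every hit passing the threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .core import CnvDbRecord, GenomicInterval

DEFAULT_THRESHOLD = 70.0


@dataclass(frozen=True)
class OverlapHit:
    query: GenomicInterval
    record: CnvDbRecord
    mutual_overlap: float
    query_coverage: float
    record_coverage: float


def mutual_overlap(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float, float]:
    """(mutual, coverage of a, coverage of b) as percentages in [0, 100].

    Different chromosomes give all zeros.
    """
    ov = a.overlap_bp(b)
    cov_a = 100.0 * ov / a.length
    cov_b = 100.0 * ov / b.length
    return min(cov_a, cov_b), cov_a, cov_b


@dataclass(frozen=True)
class BestHitsResult:
    best_by_db: dict[str, OverlapHit]
    all_hits: list[OverlapHit]  # every passing hit, mutual descending


def group_by_db(records: Iterable[CnvDbRecord]) -> dict[str, list[CnvDbRecord]]:
    out: dict[str, list[CnvDbRecord]] = {}
    for r in records:
        out.setdefault(r.source_db, []).append(r)
    return out


def best_hits(
    query: GenomicInterval,
    cnv_type: str,
    dbs: Mapping[str, Sequence[CnvDbRecord]],
    threshold: float = DEFAULT_THRESHOLD,
) -> BestHitsResult:
    """Best passing hit per database plus the full passing-hit table.

    Candidates must match the query's cnv_type (loss vs gain) and reach the
    mutual-overlap threshold.  Ties for best are broken by higher record
    coverage, then lexicographic record_id, for deterministic output.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    best: dict[str, OverlapHit] = {}
    all_hits: list[OverlapHit] = []
    for db, records in dbs.items():
        for rec in records:
            if rec.cnv_type != cnv_type:
                continue
            mutual, cov_q, cov_r = mutual_overlap(query, rec.interval)
            if mutual < threshold:
                continue
            hit = OverlapHit(query, rec, mutual, cov_q, cov_r)
            all_hits.append(hit)
            cur = best.get(db)
            if cur is None or _best_key(hit) > _best_key(cur):
                best[db] = hit
    all_hits.sort(
        key=lambda h: (-h.mutual_overlap, h.record.source_db, h.record.record_id)
    )
    return BestHitsResult(best, all_hits)


def _best_key(h: OverlapHit) -> tuple:
    # record_id descending lexicographic would be wrong; invert via negative
    # ordinal trick is overkill — compare on (mutual, record_coverage) and
    # break remaining ties by *smaller* record_id winning
    return (h.mutual_overlap, h.record_coverage, _NegStr(h.record.record_id))


class _NegStr:
    """Wrapper making lexicographically smaller strings compare greater."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_NegStr") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s
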