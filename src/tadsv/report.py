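"""Interpretation-table assembly, ISCN-style naming, run summaries and
TSV/XLSX output.

ISCN support covers the minimal grammar for the five SV types:
translocation t(C1;C2)(band1;band2), inversion inv(C)(band1band2), array
CNV arr[BUILD]Cband(start_end)xN with comma-grouped 1-based coordinates
and same-band collapsing, and the del/dup shorthand.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import CytobandRecord, GenomicInterval, StructuralVariant, ValidationError


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


class BandLookup:
    """Cytoband lookup: 0-based position -> band label."""

    def __init__(self, bands: Sequence[CytobandRecord]):
        self._by_chrom: dict[str, list[CytobandRecord]] = {}
        for b in sorted(bands, key=lambda b: (b.interval.chrom, b.interval.start)):
            self._by_chrom.setdefault(b.interval.chrom, []).append(b)

    def band_at(self, chrom: str, pos: int) -> str:
        for b in self._by_chrom.get(chrom, []):
            if b.interval.contains_pos(pos):
                return b.band
        raise ValidationError(f"position {chrom}:{pos} outside cytoband coverage")


def _grouped(n: int) -> str:
    return f"{n:,}"


def format_iscn(
    sv: StructuralVariant,
    cytobands: Sequence[CytobandRecord] | BandLookup,
    build: str = "",
    style: str = "arr",
) -> str:
    """ISCN-style string for an SV.

    CNVs default to array nomenclature (``style='arr'``); pass
    ``style='shorthand'`` for the del/dup form.  Coordinates print 1-based
    inclusive with thousands separators.
    """
    lookup = cytobands if isinstance(cytobands, BandLookup) else BandLookup(cytobands)
    build = build or sv.genome_build
    if sv.sv_type == "translocation":
        b1, b2 = sv.breakpoints
        return (
            f"t({_strip_chr(b1.chrom)};{_strip_chr(b2.chrom)})"
            f"({lookup.band_at(b1.chrom, b1.pos)};{lookup.band_at(b2.chrom, b2.pos)})"
        )
    if sv.sv_type == "inversion":
        b1, b2 = sv.breakpoints
        return (
            f"inv({_strip_chr(b1.chrom)})"
            f"({lookup.band_at(b1.chrom, b1.pos)}{lookup.band_at(b2.chrom, b2.pos)})"
        )
    if sv.sv_type in {"deletion", "duplication", "region"}:
        assert sv.span is not None
        span = sv.span
        band1 = lookup.band_at(span.chrom, span.start)
        band2 = lookup.band_at(span.chrom, span.end - 1)
        bands = band1 if band1 == band2 else f"{band1}{band2}"
        chrom = _strip_chr(span.chrom)
        if sv.sv_type == "region":
            return f"{chrom}{bands}({_grouped(span.display_start)}_{_grouped(span.display_end)})"
        if style == "shorthand":
            kind = "del" if sv.sv_type == "deletion" else "dup"
            return f"{kind}({chrom})({bands})"
        copies = 1 if sv.sv_type == "deletion" else 3
        return (
            f"arr[{build}]{chrom}{bands}"
            f"({_grouped(span.display_start)}_{_grouped(span.display_end)})x{copies}"
        )
    if sv.sv_type == "insertion":
        bp = sv.breakpoints[0]
        return f"ins({_strip_chr(bp.chrom)})({lookup.band_at(bp.chrom, bp.pos)})"
    raise ValueError(f"unsupported sv_type {sv.sv_type}")


def sv_length_label(span: GenomicInterval) -> str:
    """Human length string: nearest kb below 1 Mb, else nearest 0.1 Mb."""
    length = span.length
    if length < 1_000_000:
        return f"{round(length / 1000)} kb"
    return f"{length / 1_000_000:.1f} Mb"


@dataclass(frozen=True)
class RunSummary:
    original_counts: dict[str, int]
    reanalyzed_counts: dict[str, int]
    total: int
    vus_reduction_percent: Optional[int]
    concordance_percent: float
    original_vus_share_percent: float


def summarize_run(
    original: Mapping[str, str], reanalyzed: Mapping[str, str]
) -> RunSummary:
    """Compare original vs reanalysed categories for the same SV ids.

    VUS reduction is 100*(V0-V1)/V0 rounded to the nearest integer (empty
    when V0 = 0); concordance and the original-VUS share are 1-decimal
    percentages.
    """
    if set(original) != set(reanalyzed):
        raise ValueError("original and reanalyzed call sets must share SV ids")
    total = len(original)
    if total == 0:
        raise ValueError("empty call sets")
    orig_counts: dict[str, int] = {}
    re_counts: dict[str, int] = {}
    for v in original.values():
        orig_counts[v] = orig_counts.get(v, 0) + 1
    for v in reanalyzed.values():
        re_counts[v] = re_counts.get(v, 0) + 1
    v0 = orig_counts.get("vus", 0)
    v1 = re_counts.get("vus", 0)
    reduction = round(100.0 * (v0 - v1) / v0) if v0 else None
    equal = sum(1 for k in original if original[k] == reanalyzed[k])
    return RunSummary(
        original_counts=orig_counts,
        reanalyzed_counts=re_counts,
        total=total,
        vus_reduction_percent=reduction,
        concordance_percent=round(100.0 * equal / total, 1),
        original_vus_share_percent=round(100.0 * v0 / total, 1),
    )


REPORT_COLUMNS = [
    "sv_id", "iscn", "sv_length", "region_kind", "region_offset",
    "region_interval", "element_id", "element_symbol", "element_biotype",
    "pli", "oe_lof", "haploinsufficient", "triplosensitive",
    "disrupted_by_breakpoint", "loops_disrupted", "loops_total",
    "cluster_disrupted", "disorders",
    "phenssc", "maxssc", "p_value",
    "best_hit_db", "best_hit_id", "best_hit_classification",
    "best_hit_mutual_overlap", "best_hit_frequency",
    "acmg_evidence", "acmg_score", "acmg_class",
    "category", "ucsc_url",
]

OVERLAP_COLUMNS = [
    "query_id", "source_db", "record_id", "classification", "frequency",
    "mutual_overlap", "query_coverage", "record_coverage",
]


def rows_to_frame(rows: Sequence[Mapping[str, object]]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[REPORT_COLUMNS].fillna("")


def summary_to_frame(summary: RunSummary) -> pd.DataFrame:
    rows = [
        {"metric": "total_svs", "value": summary.total},
        {
            "metric": "vus_reduction_percent",
            "value": "" if summary.vus_reduction_percent is None
            else summary.vus_reduction_percent,
        },
        {"metric": "concordance_percent", "value": summary.concordance_percent},
        {
            "metric": "original_vus_share_percent",
            "value": summary.original_vus_share_percent,
        },
    ]
    for cat, n in sorted(summary.original_counts.items()):
        rows.append({"metric": f"original_{cat}", "value": n})
    for cat, n in sorted(summary.reanalyzed_counts.items()):
        rows.append({"metric": f"reanalyzed_{cat}", "value": n})
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_outputs(
    rows: Sequence[Mapping[str, object]],
    path_prefix: str | Path,
    formats: Sequence[str] = ("tsv",),
    summary: Optional[RunSummary] = None,
    overlap_rows: Optional[Sequence[Mapping[str, object]]] = None,
) -> list[Path]:
    """Write the interpretation table (and optional summary / detailed
    overlap tables) as TSV and/or XLSX with a fixed column order.

    TSV output is byte-stable across runs with the same inputs.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables: list[tuple[str, pd.DataFrame]] = []
    if rows:
        tables.append(("interpretation", rows_to_frame(rows)))
    if summary is not None:
        tables.append(("summary", summary_to_frame(summary)))
    if overlap_rows is not None:
        df = pd.DataFrame(list(overlap_rows))
        for col in OVERLAP_COLUMNS:
            if col not in df.columns:
                df[col] = ""
        tables.append(("overlap_details", df[OVERLAP_COLUMNS].fillna("")))
    if not tables:
        raise ValueError("nothing to write: no rows and no summary")
    for fmt in formats:
        if fmt == "tsv":
            for name, df in tables:
                out = prefix.with_name(f"{prefix.name}_{name}.tsv")
                df.to_csv(out, sep="\t", index=False)
                written.append(out)
        elif fmt == "xlsx":
            out = prefix.with_name(f"{prefix.name}.xlsx")
            with pd.ExcelWriter(out, engine="openpyxl") as xl:
                for name, df in tables:
                    df.to_excel(xl, sheet_name=name, index=False)
            written.append(out)
        else:
            raise ValueError(f"unknown output format {fmt!r}")
    return written
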