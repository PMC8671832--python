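"""Core domain types shared across the package.

All internal coordinates are 0-based half-open; anything the user types or
reads in a report (ISCN strings, UCSC positions, variant TSVs) is 1-based
inclusive.  ``GenomicInterval.display_start`` / ``display_end`` perform the
conversion in one place so interval arithmetic never mixes conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

BIOTYPES = frozenset(
    {"protein_coding", "lincRNA", "lncRNA", "other_functional", "non_functional"}
)
#: biotypes kept by the remaining-region element filter even without an
#: expression pattern
REMAINING_REGION_BIOTYPES = frozenset({"protein_coding", "lincRNA", "lncRNA"})

SV_TYPES = frozenset(
    {"translocation", "inversion", "deletion", "duplication", "insertion", "region"}
)
CNV_TYPES = frozenset({"loss", "gain"})
CLASSIFICATIONS = (
    "benign",
    "likely_benign",
    "vus",
    "likely_pathogenic",
    "pathogenic",
)
INHERITANCE_MODES = frozenset({"AD", "AR", "XL", "other"})

#: minimum SV span analysed (bp); smaller CNVs are rejected at construction
MIN_SV_SIZE = 1000


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome, 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def display_start(self) -> int:
        """1-based inclusive start as printed in reports."""
        return self.start + 1

    @property
    def display_end(self) -> int:
        """1-based inclusive end (equals the half-open end coordinate)."""
        return self.end

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @classmethod
    def from_display(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (user input)."""
        return cls(chrom, start1 - 1, end1)


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("breakpoint chromosome must be non-empty")
        if self.pos < 0:
            raise ValidationError(f"breakpoint position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class TadRecord:
    interval: GenomicInterval
    tissue: str
    index: int


@dataclass(frozen=True)
class LoopRecord:
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValidationError("loop anchors must share a chromosome")
        if self.anchor_a.end > self.anchor_b.start:
            raise ValidationError("loop anchors must be ordered and disjoint")


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    name: str
    inheritance: str
    hpo_terms: frozenset[str]

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValidationError(
                f"unknown inheritance mode {self.inheritance!r} for {self.disease_id}"
            )


@dataclass(frozen=True)
class DiseaseLink:
    """A gene-to-disease link carrying the inheritance mode of that link."""

    disease_id: str
    inheritance: str


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    span: GenomicInterval
    strand: str
    biotype: str
    pli: Optional[float] = None
    oe_lof: Optional[float] = None
    haploinsufficient: bool = False
    triplosensitive: bool = False
    has_expression_pattern: bool = False
    disorders: tuple[DiseaseLink, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"gene {self.gene_id}: biotype {self.biotype!r} not in {sorted(BIOTYPES)}"
            )
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValidationError(f"gene {self.gene_id}: pli {self.pli} outside [0,1]")
        if self.oe_lof is not None and self.oe_lof < 0:
            raise ValidationError(f"gene {self.gene_id}: oe_lof {self.oe_lof} < 0")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class RegClusterRecord:
    """A gene with its curated set of interacting regulatory elements
    (enhancers plus the gene's own TSS interval)."""

    target_gene: str
    elements: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValidationError(
                f"cluster for {self.target_gene}: need >= 2 elements"
            )
        chroms = {e.chrom for e in self.elements}
        if len(chroms) != 1:
            raise ValidationError(
                f"cluster for {self.target_gene}: elements span chromosomes {sorted(chroms)}"
            )

    @property
    def chrom(self) -> str:
        return self.elements[0].chrom

    @property
    def hull(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.elements),
            max(e.end for e in self.elements),
        )


@dataclass(frozen=True)
class CnvDbRecord:
    interval: GenomicInterval
    cnv_type: str
    classification: str
    frequency: Optional[float]
    source_db: str
    record_id: str

    def __post_init__(self) -> None:
        if self.frequency is not None and not (0.0 <= self.frequency <= 1.0):
            raise ValidationError(
                f"CNV record {self.record_id}: frequency {self.frequency} outside [0,1]"
            )


@dataclass(frozen=True)
class CytobandRecord:
    interval: GenomicInterval
    band: str
    stain: str


@dataclass(frozen=True)
class StructuralVariant:
    """A typed SV entering the interpretation pipeline.

    Breakpoint/span layout per type: translocation — one breakpoint per
    chromosome; inversion — two ordered breakpoints on one chromosome;
    deletion/duplication — a span (breakpoints derived from its ends);
    insertion — acceptor breakpoint plus optional donor start/end (up to 3);
    region — a bare span analysed without an SV model.
    """

    sv_type: str
    breakpoints: tuple[Breakpoint, ...] = ()
    span: Optional[GenomicInterval] = None
    genome_build: str = "GRCh37"
    tissue: str = "hESC"
    sv_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")
        t = self.sv_type
        bps = self.breakpoints
        if t == "translocation":
            if len(bps) != 2 or bps[0].chrom == bps[1].chrom:
                raise ValidationError(
                    "translocation needs two breakpoints on different chromosomes"
                )
        elif t == "inversion":
            if len(bps) != 2 or bps[0].chrom != bps[1].chrom:
                raise ValidationError(
                    "inversion needs two breakpoints on one chromosome"
                )
            if bps[0].pos >= bps[1].pos:
                raise ValidationError("inversion breakpoints must be ordered")
        elif t in {"deletion", "duplication"}:
            if self.span is None:
                raise ValidationError(f"{t} requires a span")
            if self.span.length <= MIN_SV_SIZE:
                raise ValidationError(
                    f"{t} span must exceed {MIN_SV_SIZE} bp, got {self.span.length}"
                )
        elif t == "insertion":
            if not 1 <= len(bps) <= 3:
                raise ValidationError("insertion needs 1-3 breakpoints")
        elif t == "region":
            if self.span is None:
                raise ValidationError("region mode requires a span")

    @property
    def cnv_type(self) -> Optional[str]:
        return {"deletion": "loss", "duplication": "gain"}.get(self.sv_type)

    @property
    def is_cnv(self) -> bool:
        return self.sv_type in {"deletion", "duplication"}

    @property
    def is_balanced(self) -> bool:
        return self.sv_type in {"translocation", "inversion", "insertion"}

    def effective_breakpoints(self) -> tuple[Breakpoint, ...]:
        """Breakpoints to resolve: explicit ones, or the span ends for CNVs."""
        if self.is_cnv:
            assert self.span is not None
            return (
                Breakpoint(self.span.chrom, self.span.start, "span start"),
                Breakpoint(self.span.chrom, self.span.end - 1, "span end"),
            )
        return self.breakpoints


def check_single_chrom_style(chroms: Sequence[str]) -> None:
    """Reject runs that mix 'chr'-prefixed and bare chromosome names."""
    styles = {c.startswith("chr") for c in chroms if c}
    if len(styles) > 1:
        raise ValidationError(
            "mixed chromosome naming styles ('chr1' vs '1') within one run"
        )
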