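"""Readers and writers for every annotation dialect the tool consumes.

All files are plain TSV (or OBO for the ontology).  Coordinates on disk are
0-based half-open for annotation files; variant TSVs carry 1-based inclusive
positions, converted on ingest.  Unknown CNV classification labels are
coerced to ``unclassified`` with a logged warning rather than dropped.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Optional

import obonet
import networkx as nx

from .core import (
    Breakpoint,
    CnvDbRecord,
    CytobandRecord,
    DiseaseLink,
    DiseaseRecord,
    GeneRecord,
    GenomicInterval,
    LoopRecord,
    ParseError,
    RegClusterRecord,
    StructuralVariant,
    TadRecord,
    ValidationError,
    CLASSIFICATIONS,
)

log = logging.getLogger(__name__)

_KNOWN_CLASSIFICATIONS = set(CLASSIFICATIONS) | {"unclassified"}


def _rows(path: str | Path, min_cols: int, skip_header: Optional[str] = None):
    """Yield (line_number, fields) for non-empty, non-comment lines."""
    path = Path(path)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if skip_header is not None and i == 1 and fields[0] == skip_header:
                continue
            if len(fields) < min_cols:
                raise ParseError(
                    f"expected >= {min_cols} columns, got {len(fields)}",
                    str(path),
                    i,
                )
            yield i, fields


def _int(value: str, what: str, path: str, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"non-integer {what} {value!r}", path, line) from None


def read_tads(path: str | Path, tissue: str) -> list[TadRecord]:
    """Read a TAD BED-like TSV (chrom, start, end) for one tissue.

    Records are sorted by (chrom, start), per-chromosome indices assigned
    from 0, and overlapping TADs rejected.
    """
    intervals: list[GenomicInterval] = []
    for i, f in _rows(path, 3, skip_header="chrom"):
        iv = GenomicInterval(
            f[0],
            _int(f[1], "start", str(path), i),
            _int(f[2], "end", str(path), i),
        )
        intervals.append(iv)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    records: list[TadRecord] = []
    counters: dict[str, int] = defaultdict(int)
    prev: dict[str, GenomicInterval] = {}
    for iv in intervals:
        p = prev.get(iv.chrom)
        if p is not None and iv.start < p.end:
            raise ValidationError(
                f"overlapping TADs on {iv.chrom}: "
                f"[{p.start},{p.end}) and [{iv.start},{iv.end})"
            )
        prev[iv.chrom] = iv
        records.append(TadRecord(iv, tissue, counters[iv.chrom]))
        counters[iv.chrom] += 1
    return records


def write_tads(path: str | Path, tads: Iterable[TadRecord]) -> None:
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\n")


def read_loops(path: str | Path, tissue: str = "") -> list[LoopRecord]:
    """Read a BEDPE-style loop file (chrom1,start1,end1,chrom2,start2,end2)."""
    loops = []
    for i, f in _rows(path, 6, skip_header="chrom1"):
        a = GenomicInterval(f[0], _int(f[1], "start1", str(path), i), _int(f[2], "end1", str(path), i))
        b = GenomicInterval(f[3], _int(f[4], "start2", str(path), i), _int(f[5], "end2", str(path), i))
        loops.append(LoopRecord(a, b, tissue))
    return loops


def write_loops(path: str | Path, loops: Iterable[LoopRecord]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}\t"
                f"{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}\n"
            )


GENE_COLUMNS = [
    "gene_id", "symbol", "chrom", "start", "end", "strand", "biotype",
    "pli", "oe_lof", "haploinsufficient", "triplosensitive",
    "has_expression_pattern", "disorders",
]


def _parse_bool(v: str) -> bool:
    return v.strip().lower() in {"1", "true", "yes", "y"}


def _parse_optional_float(v: str) -> Optional[float]:
    v = v.strip()
    if v in {"", ".", "NA", "nan"}:
        return None
    x = float(v)
    if math.isnan(x):
        return None
    return x


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read the gene metadata TSV (header required, see GENE_COLUMNS)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    missing = [c for c in GENE_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"gene file missing mandatory columns {missing}", str(path), 1)
    idx = {c: header.index(c) for c in GENE_COLUMNS}
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if i == 1 or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < len(header):
                raise ParseError(f"short row ({len(f)} columns)", str(path), i)
            disorders = []
            raw = f[idx["disorders"]].strip()
            if raw:
                for pair in raw.split(";"):
                    # disease ids may themselves contain colons (OMIM:123456)
                    did, sep, mode = pair.rpartition(":")
                    if not sep:
                        did, mode = pair, "other"
                    disorders.append(DiseaseLink(did, mode or "other"))
            genes.append(
                GeneRecord(
                    gene_id=f[idx["gene_id"]],
                    symbol=f[idx["symbol"]],
                    span=GenomicInterval(
                        f[idx["chrom"]],
                        _int(f[idx["start"]], "start", str(path), i),
                        _int(f[idx["end"]], "end", str(path), i),
                    ),
                    strand=f[idx["strand"]],
                    biotype=f[idx["biotype"]],
                    pli=_parse_optional_float(f[idx["pli"]]),
                    oe_lof=_parse_optional_float(f[idx["oe_lof"]]),
                    haploinsufficient=_parse_bool(f[idx["haploinsufficient"]]),
                    triplosensitive=_parse_bool(f[idx["triplosensitive"]]),
                    has_expression_pattern=_parse_bool(f[idx["has_expression_pattern"]]),
                    disorders=tuple(disorders),
                )
            )
    return genes


def write_genes(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            disorders = ";".join(f"{d.disease_id}:{d.inheritance}" for d in g.disorders)
            fh.write(
                "\t".join(
                    [
                        g.gene_id, g.symbol, g.span.chrom,
                        str(g.span.start), str(g.span.end), g.strand, g.biotype,
                        "" if g.pli is None else repr(g.pli),
                        "" if g.oe_lof is None else repr(g.oe_lof),
                        str(g.haploinsufficient).lower(),
                        str(g.triplosensitive).lower(),
                        str(g.has_expression_pattern).lower(),
                        disorders,
                    ]
                )
                + "\n"
            )


def read_clusters(path: str | Path) -> list[RegClusterRecord]:
    """Read regulatory-interaction clusters (target_gene, chrom, start, end;
    one element per row)."""
    by_gene: dict[str, list[GenomicInterval]] = defaultdict(list)
    order: list[str] = []
    for i, f in _rows(path, 4, skip_header="target_gene"):
        gene = f[0]
        if gene not in by_gene:
            order.append(gene)
        by_gene[gene].append(
            GenomicInterval(f[1], _int(f[2], "element_start", str(path), i), _int(f[3], "element_end", str(path), i))
        )
    return [RegClusterRecord(g, tuple(by_gene[g])) for g in order]


def write_clusters(path: str | Path, clusters: Iterable[RegClusterRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("target_gene\tchrom\telement_start\telement_end\n")
        for c in clusters:
            for e in c.elements:
                fh.write(f"{c.target_gene}\t{e.chrom}\t{e.start}\t{e.end}\n")


def read_cnv_db(path: str | Path) -> list[CnvDbRecord]:
    """Read a curated CNV database snapshot.

    Columns: chrom, start, end, cnv_type, classification, frequency,
    source_db, record_id.  Unknown classification labels are coerced to
    ``unclassified`` (logged), never dropped.
    """
    records = []
    for i, f in _rows(path, 8, skip_header="chrom"):
        classification = f[4].strip().lower()
        if classification not in _KNOWN_CLASSIFICATIONS:
            log.warning(
                "%s:%d unknown classification %r coerced to 'unclassified'",
                path, i, f[4],
            )
            classification = "unclassified"
        records.append(
            CnvDbRecord(
                interval=GenomicInterval(f[0], _int(f[1], "start", str(path), i), _int(f[2], "end", str(path), i)),
                cnv_type=f[3],
                classification=classification,
                frequency=_parse_optional_float(f[5]),
                source_db=f[6],
                record_id=f[7],
            )
        )
    return records


def write_cnv_db(path: str | Path, records: Iterable[CnvDbRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcnv_type\tclassification\tfrequency\tsource_db\trecord_id\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom, str(r.interval.start), str(r.interval.end),
                        r.cnv_type, r.classification,
                        "" if r.frequency is None else repr(r.frequency),
                        r.source_db, r.record_id,
                    ]
                )
                + "\n"
            )


def read_cytobands(path: str | Path) -> list[CytobandRecord]:
    """Read a UCSC cytoBand.txt-layout file (chrom, start, end, band, stain).

    Bands must tile each chromosome without gaps or overlap.
    """
    records = []
    for i, f in _rows(path, 5, skip_header="chrom"):
        records.append(
            CytobandRecord(
                GenomicInterval(f[0], _int(f[1], "start", str(path), i), _int(f[2], "end", str(path), i)),
                f[3],
                f[4],
            )
        )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    prev: dict[str, CytobandRecord] = {}
    for r in records:
        p = prev.get(r.interval.chrom)
        if p is not None and r.interval.start != p.interval.end:
            raise ValidationError(
                f"cytobands on {r.interval.chrom} do not tile: "
                f"{p.band} ends at {p.interval.end}, {r.band} starts at {r.interval.start}"
            )
        prev[r.interval.chrom] = r
    return records


def write_cytobands(path: str | Path, records: Iterable[CytobandRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.band}\t{r.stain}\n"
            )


def read_ontology(obo_path: str | Path, annotations_path: str | Path):
    """Build an :class:`~tadsv.phenosim.OntologyGraph` from an OBO file plus
    an HPOA-like disease-annotation TSV (disease_id, disease_name,
    inheritance, term_id; one term per row).

    The is_a edges must form a DAG with a single root; annotations to terms
    absent from the OBO are errors.
    """
    from .phenosim import OntologyGraph  # local import to avoid a cycle

    graph = obonet.read_obo(str(obo_path))
    # obonet edges point child -> parent for is_a
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValidationError(f"ontology is_a edges contain a cycle: {cycle}")
    roots = [n for n in dag.nodes if dag.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValidationError(f"ontology must have exactly one root, found {roots}")

    diseases: dict[str, DiseaseRecord] = {}
    terms_by_disease: dict[str, set[str]] = defaultdict(set)
    meta: dict[str, tuple[str, str]] = {}
    for i, f in _rows(annotations_path, 4, skip_header="disease_id"):
        did, name, inheritance, term = f[0], f[1], f[2], f[3]
        if term not in dag.nodes:
            raise ValidationError(
                f"disease {did} annotated to unknown term {term}"
            )
        terms_by_disease[did].add(term)
        meta[did] = (name, inheritance)
    for did, terms in terms_by_disease.items():
        name, inheritance = meta[did]
        diseases[did] = DiseaseRecord(did, name, inheritance, frozenset(terms))
    return OntologyGraph.from_dag(dag, diseases, root=roots[0])


VARIANT_COLUMNS = [
    "sv_id", "sv_type", "chrom1", "pos1", "chrom2", "pos2",
    "span_start", "span_end", "genome_build", "tissue",
]


def read_variants(path: str | Path) -> list[StructuralVariant]:
    """Read the batch variant TSV (1-based positions)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    missing = [c for c in VARIANT_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"variant file missing columns {missing}", str(path), 1)
    idx = {c: header.index(c) for c in VARIANT_COLUMNS}
    svs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if i == 1 or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sv_type = f[idx["sv_type"]]
            bps: list[Breakpoint] = []
            if f[idx["chrom1"]] and f[idx["pos1"]]:
                bps.append(Breakpoint(f[idx["chrom1"]], int(f[idx["pos1"]]) - 1))
            if f[idx["chrom2"]] and f[idx["pos2"]]:
                bps.append(Breakpoint(f[idx["chrom2"]], int(f[idx["pos2"]]) - 1))
            span = None
            if f[idx["span_start"]] and f[idx["span_end"]]:
                chrom = f[idx["chrom1"]] or (bps[0].chrom if bps else "")
                span = GenomicInterval.from_display(
                    chrom, int(f[idx["span_start"]]), int(f[idx["span_end"]])
                )
            svs.append(
                StructuralVariant(
                    sv_type=sv_type,
                    breakpoints=tuple(bps),
                    span=span,
                    genome_build=f[idx["genome_build"]],
                    tissue=f[idx["tissue"]],
                    sv_id=f[idx["sv_id"]],
                )
            )
    return svs


def write_variants(path: str | Path, svs: Iterable[StructuralVariant]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for sv in svs:
            bps = sv.breakpoints
            c1 = bps[0].chrom if len(bps) > 0 else (sv.span.chrom if sv.span else "")
            p1 = str(bps[0].pos + 1) if len(bps) > 0 else ""
            c2 = bps[1].chrom if len(bps) > 1 else ""
            p2 = str(bps[1].pos + 1) if len(bps) > 1 else ""
            s1 = str(sv.span.display_start) if sv.span else ""
            s2 = str(sv.span.display_end) if sv.span else ""
            fh.write(
                "\t".join(
                    [sv.sv_id, sv.sv_type, c1, p1, c2, p2, s1, s2, sv.genome_build, sv.tissue]
                )
                + "\n"
            )
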