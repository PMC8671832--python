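"""Seeded synthetic-data generator: a complete miniature input universe.

``make_toy_genome`` writes every file dialect the tool reads — TAD grid,
chromatin loops, gene metadata, regulatory clusters, cytobands, a curated
CNV database snapshot, a small ontology with disease annotations — plus a
JSON manifest of planted truths that is re-derived with independent
brute-force code before being written.  The universe embeds two planted
scenarios:

* a deletion spanning five protein-coding genes with no dosage-sensitivity
  evidence and a 100%-mutual-overlap likely-benign database record (the
  automated dosage rubric resolves it to -0.90, likely benign);
* a position-effect scenario: a dominant-disorder gene whose regulatory
  cluster and three of four chromatin loops straddle a planted intergenic
  breakpoint.

The toy ontology (12 terms, 4 diseases) is built so the similarity scores
have closed forms: leaf ICs of ln 2 and ln 4, branch MICA IC of ln(4/3),
and an exact exhaustive permutation p of 1/6 for the two-term query
against disease D1.

``make_random_suite`` emits a batch variant TSV of random SVs of all five
types together with expected brTADs, best database hits and rule-engine
categories derived by brute-force linear scans (never by the indexed code
paths under test).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .core import (
    Breakpoint,
    CnvDbRecord,
    CytobandRecord,
    DiseaseLink,
    GeneRecord,
    GenomicInterval,
    LoopRecord,
    RegClusterRecord,
    StructuralVariant,
)

CHROM_SIZES = {"chr1": 600_000, "chr2": 400_000}
TAD_SIZE = 100_000
TISSUE = "hESC"
BUILD = "GRCh37"

ROOT = "HP:0000001"
TERM_A, TERM_B = "HP:0000010", "HP:0000020"
A1, A2, B1, B2 = "HP:0000011", "HP:0000012", "HP:0000021", "HP:0000022"
PADDING = ["HP:0000030", "HP:0000031", "HP:0000032", "HP:0000033", "HP:0000034"]

#: disease -> (name, inheritance, directly annotated terms)
DISEASES = {
    "OMIM:100100": ("Syndrome alpha", "AD", [A1, A2]),
    "OMIM:200200": ("Syndrome beta", "AR", [A1, B1]),
    "OMIM:300300": ("Syndrome gamma", "AR", [B2]),
    "OMIM:400400": ("Syndrome delta", "AD", [B1, B2]),
}

PLANTED_BREAKPOINT = Breakpoint("chr1", 150_000, "planted position-effect bp")
CK_SPAN = GenomicInterval("chr2", 50_000, 160_000)


@dataclass
class FixtureManifest:
    seed: int
    files: dict[str, str]            # role -> path
    counts: dict[str, int]           # role -> record count
    planted: dict[str, object]       # truths validated at generation time
    sha256: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "files": self.files,
                "counts": self.counts,
                "planted": self.planted,
                "sha256": self.sha256,
            },
            indent=2,
            sort_keys=True,
        )


def _build_tads() -> list[tuple[str, int, int]]:
    rows = []
    for chrom, size in CHROM_SIZES.items():
        for start in range(0, size, TAD_SIZE):
            rows.append((chrom, start, start + TAD_SIZE))
    return rows


def _build_genes(rng: np.random.Generator) -> list[GeneRecord]:
    genes: list[GeneRecord] = [
        # position-effect candidate: AD disorder, high pLI, cluster + loops
        GeneRecord(
            "G_PE", "PEX1L", GenomicInterval("chr1", 160_000, 180_000), "+",
            "protein_coding", pli=0.99, oe_lof=0.12,
            disorders=(DiseaseLink("OMIM:100100", "AD"),),
            has_expression_pattern=True,
        ),
        # AR-only gene in TAD0
        GeneRecord(
            "G_AR", "ARX2L", GenomicInterval("chr1", 10_000, 30_000), "-",
            "protein_coding", pli=0.02, oe_lof=0.9,
            disorders=(DiseaseLink("OMIM:300300", "AR"),),
        ),
        # constrained gene with no disorder link in TAD2
        GeneRecord(
            "G_PLI", "PLIX1", GenomicInterval("chr1", 210_000, 230_000), "+",
            "protein_coding", pli=0.95, oe_lof=0.2,
        ),
        # non-functional element without expression pattern in TAD3
        GeneRecord(
            "E_NF", "NFELEM1", GenomicInterval("chr1", 310_000, 320_000), "+",
            "non_functional",
        ),
        # lincRNA with expression pattern in TAD4
        GeneRecord(
            "G_LINC", "LINC01X", GenomicInterval("chr1", 410_000, 420_000), "-",
            "lincRNA", has_expression_pattern=True,
        ),
    ]
    # the five deleted genes of the dosage worked example (chr2)
    starts = [55_000, 70_000, 90_000, 110_000, 140_000]
    ends = [60_000, 75_000, 95_000, 120_000, 150_000]
    for i, (s, e) in enumerate(zip(starts, ends), start=1):
        genes.append(
            GeneRecord(
                f"G_CK{i}", f"CKG{i}", GenomicInterval("chr2", s, e), "+",
                "protein_coding",
                pli=round(float(rng.uniform(0.0, 0.4)), 3),
                oe_lof=round(float(rng.uniform(0.5, 1.2)), 3),
            )
        )
    # one gene outside the deletion span on chr2
    genes.append(
        GeneRecord(
            "G_OUT", "OUTG1", GenomicInterval("chr2", 250_000, 270_000), "+",
            "protein_coding", pli=0.5, oe_lof=0.4,
        )
    )
    return genes


def _build_loops() -> list[LoopRecord]:
    # three loops of G_PE disrupted by the planted breakpoint (anchors on
    # opposite sides of 150 kb), one intact loop inside the gene body
    return [
        LoopRecord(GenomicInterval("chr1", 105_000, 110_000), GenomicInterval("chr1", 160_000, 165_000), TISSUE),
        LoopRecord(GenomicInterval("chr1", 112_000, 117_000), GenomicInterval("chr1", 166_000, 171_000), TISSUE),
        LoopRecord(GenomicInterval("chr1", 120_000, 125_000), GenomicInterval("chr1", 172_000, 177_000), TISSUE),
        LoopRecord(GenomicInterval("chr1", 162_000, 164_000), GenomicInterval("chr1", 170_000, 172_000), TISSUE),
    ]


def _build_clusters() -> list[RegClusterRecord]:
    # enhancers upstream of the planted breakpoint, TSS downstream
    return [
        RegClusterRecord(
            "G_PE",
            (
                GenomicInterval("chr1", 110_000, 115_000),
                GenomicInterval("chr1", 120_000, 125_000),
                GenomicInterval("chr1", 160_000, 162_000),
            ),
        )
    ]


def _build_cytobands() -> list[CytobandRecord]:
    return [
        CytobandRecord(GenomicInterval("chr1", 0, 200_000), "p12", "gneg"),
        CytobandRecord(GenomicInterval("chr1", 200_000, 300_000), "p11", "gpos50"),
        CytobandRecord(GenomicInterval("chr1", 300_000, 450_000), "q11", "gneg"),
        CytobandRecord(GenomicInterval("chr1", 450_000, 600_000), "q12", "gpos50"),
        CytobandRecord(GenomicInterval("chr2", 0, 200_000), "p11", "gneg"),
        CytobandRecord(GenomicInterval("chr2", 200_000, 400_000), "q11", "gpos50"),
    ]


def _build_cnv_db(rng: np.random.Generator) -> list[CnvDbRecord]:
    records = [
        # the dosage worked example: identical span, likely benign
        CnvDbRecord(CK_SPAN, "loss", "likely_benign", 0.002, "clingen", "nsv_ck_1"),
        # partially overlapping records for best-hit selection
        CnvDbRecord(GenomicInterval("chr2", 50_000, 140_000), "loss", "vus", 0.001, "dgv", "dgv_001"),
        CnvDbRecord(GenomicInterval("chr2", 60_000, 160_000), "loss", "benign", 0.05, "dgv", "dgv_002"),
        CnvDbRecord(GenomicInterval("chr2", 50_000, 160_000), "gain", "pathogenic", None, "decipher", "dec_101"),
        CnvDbRecord(GenomicInterval("chr1", 100_000, 200_000), "loss", "vus", 0.004, "dgv", "dgv_003"),
    ]
    # random filler records, deterministic under the seed
    for i in range(10):
        chrom = "chr1" if rng.random() < 0.5 else "chr2"
        size = int(rng.integers(20_000, 120_000))
        start = int(rng.integers(0, CHROM_SIZES[chrom] - size))
        records.append(
            CnvDbRecord(
                GenomicInterval(chrom, start, start + size),
                "loss" if rng.random() < 0.5 else "gain",
                ["benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic"][int(rng.integers(0, 5))],
                round(float(rng.uniform(0.0, 0.03)), 4),
                ["dgv", "decipher", "clingen"][int(rng.integers(0, 3))],
                f"rnd_{i:03d}",
            )
        )
    return records


def _build_universe(seed: int):
    """The full record universe for a genome seed; one RNG stream so the
    emitted files are reproducible from the seed alone."""
    rng = np.random.default_rng(seed)
    return {
        "tad_rows": _build_tads(),
        "genes": _build_genes(rng),
        "loops": _build_loops(),
        "clusters": _build_clusters(),
        "cytobands": _build_cytobands(),
        "cnv_db": _build_cnv_db(rng),
    }


def _write_obo(path: Path) -> int:
    terms = [
        (ROOT, "Phenotypic abnormality", None),
        (TERM_A, "Branch A", ROOT),
        (TERM_B, "Branch B", ROOT),
        (A1, "Leaf a1", TERM_A),
        (A2, "Leaf a2", TERM_A),
        (B1, "Leaf b1", TERM_B),
        (B2, "Leaf b2", TERM_B),
    ] + [(t, f"Padding {i}", ROOT) for i, t in enumerate(PADDING)]
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy-phenotype\n")
        for tid, name, parent in terms:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\n")
            if parent:
                fh.write(f"is_a: {parent}\n")
    return len(terms)


def _write_annotations(path: Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("disease_id\tdisease_name\tinheritance\tterm_id\n")
        for did, (name, inheritance, terms) in DISEASES.items():
            for t in terms:
                fh.write(f"{did}\t{name}\t{inheritance}\t{t}\n")
                n += 1
    return n


# --- independent brute-force oracles used to validate planted truths -------

def _brute_brtad(tad_rows, chrom: str, pos: int):
    """Linear scan; returns (index, start, end) or None for a gap."""
    idx = -1
    for c, s, e in tad_rows:
        if c != chrom:
            continue
        idx += 1
        if s <= pos < e:
            return idx, s, e
    return None


def _brute_best_hit(records, span: GenomicInterval, cnv_type: str, threshold=70.0):
    best = None
    for r in records:
        if r.cnv_type != cnv_type or r.interval.chrom != span.chrom:
            continue
        ov = max(0, min(span.end, r.interval.end) - max(span.start, r.interval.start))
        cov_q = 100.0 * ov / span.length
        cov_r = 100.0 * ov / r.interval.length
        mutual = min(cov_q, cov_r)
        if mutual < threshold:
            continue
        key = (mutual, cov_r, tuple(-ord(ch) for ch in r.record_id))
        if best is None or key > best[0]:
            best = (key, r, mutual)
    return best


def make_toy_genome(out_dir: str | Path, seed: int = 7) -> FixtureManifest:
    """Write the complete fixture universe to ``out_dir`` and return its
    manifest.  Regeneration with the same seed is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    universe = _build_universe(seed)
    tad_rows = universe["tad_rows"]
    genes = universe["genes"]
    loops = universe["loops"]
    clusters = universe["clusters"]
    cytobands = universe["cytobands"]
    cnv_db = universe["cnv_db"]

    files = {
        "tads": str(out / "tads.tsv"),
        "loops": str(out / "loops.tsv"),
        "genes": str(out / "genes.tsv"),
        "clusters": str(out / "clusters.tsv"),
        "cytobands": str(out / "cytobands.tsv"),
        "cnv_db": str(out / "cnv_db.tsv"),
        "obo": str(out / "ontology.obo"),
        "annotations": str(out / "annotations.tsv"),
    }
    with open(files["tads"], "w") as fh:
        for c, s, e in tad_rows:
            fh.write(f"{c}\t{s}\t{e}\n")
    tio.write_loops(files["loops"], loops)
    tio.write_genes(files["genes"], genes)
    tio.write_clusters(files["clusters"], clusters)
    tio.write_cytobands(files["cytobands"], cytobands)
    tio.write_cnv_db(files["cnv_db"], cnv_db)
    n_terms = _write_obo(Path(files["obo"]))
    n_annotations = _write_annotations(Path(files["annotations"]))

    # ---- validate planted truths with brute-force re-derivation ----
    br = _brute_brtad(tad_rows, PLANTED_BREAKPOINT.chrom, PLANTED_BREAKPOINT.pos)
    assert br is not None and br[0] == 1, "planted breakpoint must land in TAD 1"
    best = _brute_best_hit(cnv_db, CK_SPAN, "loss")
    assert best is not None and best[1].record_id == "nsv_ck_1", (
        "planted deletion must best-hit the likely-benign record"
    )
    assert abs(best[2] - 100.0) < 1e-9, "planted best hit must be 100% mutual"
    ck_genes = [
        g.gene_id
        for g in genes
        if g.span.chrom == CK_SPAN.chrom
        and max(0, min(g.span.end, CK_SPAN.end) - max(g.span.start, CK_SPAN.start)) > 0
    ]
    assert len(ck_genes) == 5 and not any(
        g.haploinsufficient for g in genes if g.gene_id in ck_genes
    )
    # planted ACMG expectation: 1A (0) + benign-overlap (-0.90) + 3A (0)
    planted_acmg = {"1A": 0.0, "benign-overlap": -0.90, "3A": 0.0}

    manifest = FixtureManifest(
        seed=seed,
        files=files,
        counts={
            "tads": len(tad_rows),
            "tads_chr1": sum(1 for r in tad_rows if r[0] == "chr1"),
            "tads_chr2": sum(1 for r in tad_rows if r[0] == "chr2"),
            "loops": len(loops),
            "genes": len(genes),
            "clusters": len(clusters),
            "cytobands": len(cytobands),
            "cnv_db": len(cnv_db),
            "ontology_terms": n_terms,
            "diseases": len(DISEASES),
            "annotations": n_annotations,
        },
        planted={
            "breakpoint": {
                "chrom": PLANTED_BREAKPOINT.chrom,
                "pos": PLANTED_BREAKPOINT.pos,
                "brtad_index": br[0],
                "brtad_interval": [br[1], br[2]],
                "position_effect_gene": "G_PE",
                "loops_disrupted": 3,
                "loops_total": 4,
                "cluster_disrupted": True,
            },
            "ck_deletion": {
                "chrom": CK_SPAN.chrom,
                "start": CK_SPAN.start,
                "end": CK_SPAN.end,
                "genes": sorted(ck_genes),
                "best_hit": "nsv_ck_1",
                "acmg_evidence": planted_acmg,
                "acmg_score": -0.90,
                "acmg_class": "likely_benign",
            },
        },
    )
    for role, path in files.items():
        manifest.sha256[role] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# --- random batch suite ----------------------------------------------------

_CATEGORY_TARGETS = ["pathogenic", "likely_pathogenic", "likely_benign", "benign", "vus"]


def _brute_category(genes, tad_rows, bps: list[Breakpoint]) -> str:
    """Independent rule re-derivation for balanced SVs without phenotype
    input (the position-effect arm cannot fire)."""
    disrupted = [
        g for g in genes
        if any(bp.chrom == g.span.chrom and g.span.start < bp.pos < g.span.end for bp in bps)
    ]
    if any(any(d.inheritance == "AD" for d in g.disorders) for g in disrupted):
        return "pathogenic"
    if any(g.pli is not None and g.pli >= 0.9 and not g.disorders for g in disrupted):
        return "likely_pathogenic"
    if disrupted and all(
        g.disorders and all(d.inheritance == "AR" for d in g.disorders)
        for g in disrupted
    ):
        return "likely_benign"
    if not disrupted:
        brtad_genes = []
        for bp in bps:
            hit = _brute_brtad(tad_rows, bp.chrom, bp.pos)
            if hit is None:
                continue
            _, s, e = hit
            brtad_genes += [
                g for g in genes
                if g.span.chrom == bp.chrom and max(0, min(g.span.end, e) - max(g.span.start, s)) > 0
            ]
        if not any(g.disorders for g in brtad_genes):
            return "benign"
    return "vus"


def _bp_for_category(rng: np.random.Generator, category: str) -> int:
    """A chr1 position whose rule-engine outcome is the requested category
    (jittered within the safe window)."""
    if category == "pathogenic":       # inside G_PE
        return int(rng.integers(160_001, 180_000))
    if category == "likely_pathogenic":  # inside G_PLI
        return int(rng.integers(210_001, 230_000))
    if category == "likely_benign":    # inside G_AR
        return int(rng.integers(10_001, 30_000))
    if category == "benign":           # empty TAD 5
        return int(rng.integers(500_000, 600_000))
    # vus: TAD1 outside G_PE (disorder-linked gene in brTAD, none disrupted)
    return int(rng.integers(100_000, 150_000))


def make_random_suite(
    out_dir: str | Path, seed: int = 1, n_svs: int = 50, genome_seed: int = 7
) -> tuple[Path, Path]:
    """Emit a batch variant TSV plus an expected-output TSV whose truths
    (brTAD, best hit, category) come from brute-force scans against the
    ``make_toy_genome(genome_seed)`` universe."""
    if n_svs < 1:
        raise ValueError("n_svs must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    universe = _build_universe(genome_seed)
    tad_rows = universe["tad_rows"]
    genes = universe["genes"]
    cnv_db = universe["cnv_db"]

    sv_types = ["translocation", "inversion", "deletion", "duplication", "insertion"]
    variants: list[StructuralVariant] = []
    expected: list[dict[str, object]] = []
    for i in range(n_svs):
        sv_type = sv_types[i % len(sv_types)]
        sv_id = f"SV{i:04d}"
        category_target = _CATEGORY_TARGETS[(i // len(sv_types)) % len(_CATEGORY_TARGETS)]
        if sv_type in {"deletion", "duplication"}:
            size = int(rng.integers(5_000, 150_000))
            start = int(rng.integers(0, CHROM_SIZES["chr2"] - size))
            span = GenomicInterval("chr2", start, start + size)
            sv = StructuralVariant(sv_type, span=span, sv_id=sv_id, tissue=TISSUE)
            best = _brute_best_hit(cnv_db, span, sv.cnv_type)
            row = {
                "sv_id": sv_id,
                "sv_type": sv_type,
                "expected_category": "",
                "expected_best_hit": "" if best is None else best[1].record_id,
            }
            bps = sv.effective_breakpoints()
        elif sv_type == "translocation":
            pos1 = _bp_for_category(rng, category_target)
            pos2 = int(rng.integers(0, CHROM_SIZES["chr2"]))
            # keep the chr2 breakpoint out of every chr2 gene so the chr1
            # breakpoint alone decides the category
            while any(
                g.span.chrom == "chr2" and g.span.start <= pos2 <= g.span.end + 1
                for g in genes
            ) or (category_target == "benign" and pos2 < 200_000):
                pos2 = int(rng.integers(0, CHROM_SIZES["chr2"]))
            bps = [Breakpoint("chr1", pos1), Breakpoint("chr2", pos2)]
            sv = StructuralVariant(sv_type, tuple(bps), sv_id=sv_id, tissue=TISSUE)
            row = {"sv_id": sv_id, "sv_type": sv_type,
                   "expected_category": _brute_category(genes, tad_rows, bps),
                   "expected_best_hit": ""}
        else:  # inversion / insertion on chr1
            pos1 = _bp_for_category(rng, category_target)
            if sv_type == "inversion":
                pos2 = int(rng.integers(520_000, 560_000)) if category_target == "benign" \
                    else int(rng.integers(440_000, 450_000))
                while pos2 == pos1:
                    pos2 += 1
                lo, hi = sorted((pos1, pos2))
                bps = [Breakpoint("chr1", lo), Breakpoint("chr1", hi)]
            else:
                bps = [Breakpoint("chr1", pos1)]
            sv = StructuralVariant(sv_type, tuple(bps), sv_id=sv_id, tissue=TISSUE)
            row = {"sv_id": sv_id, "sv_type": sv_type,
                   "expected_category": _brute_category(genes, tad_rows, bps),
                   "expected_best_hit": ""}
        for j, bp in enumerate(bps, start=1):
            hit = _brute_brtad(tad_rows, bp.chrom, bp.pos)
            row[f"expected_brtad_{j}"] = (
                "gap" if hit is None else f"{bp.chrom}:{hit[1]}-{hit[2]}"
            )
        row.setdefault("expected_brtad_2", "")
        variants.append(sv)
        expected.append(row)

    variants_path = out / "variants.tsv"
    expected_path = out / "expected.tsv"
    tio.write_variants(variants_path, variants)
    cols = ["sv_id", "sv_type", "expected_brtad_1", "expected_brtad_2",
            "expected_category", "expected_best_hit"]
    with open(expected_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in expected:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
    return variants_path, expected_path
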