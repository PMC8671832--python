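# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (`[start, end)`); every
user-facing coordinate — CLI input, variant TSVs, ISCN strings, UCSC
links — is 1-based inclusive. `GenomicInterval.from_display` /
`display_start` / `display_end` are the only conversion points, so
interval arithmetic never mixes conventions. Chromosome names are taken
verbatim; mixing `chr1` and `1` styles within one run is an error rather
than being silently normalised, because a silent mismatch between
annotation files produces empty (not wrong-looking) results.

## Region resolution

A breakpoint resolves to the unique TAD whose half-open interval contains
it; uniqueness follows from the per-chromosome non-overlap invariant
enforced at file ingest. TAD−k/TAD+k are numbered in coordinate order,
not transcription direction, since TADs are strand-free structures.

Breakpoints falling between TADs resolve to the inter-TAD gap itself,
flagged `boundary/gap`, rather than being attributed to either neighbour:
boundary regions restrict regulatory interactions and deserve explicit
surfacing, and attributing the breakpoint to one side would be a silent
guess. Flank offsets around a gap count outward from its two neighbours.

For CNVs the two span ends are treated as breakpoints; the interior of
the span minus the two breakpoint TADs is reported as a `remaining`
region with its stricter element filter. Insertions are modelled as up to
three breakpoints (acceptor site, donor start, donor end), each resolved
independently — no insertion-specific rule exists to do better.

Chromosomes without called TADs (chrY in the shipped references) use a
tiling of fixed windows of the tissue's average TAD size, e.g. 815 kb for
the GM12878 lymphoblastoid line; window k covers
`[k·avg, (k+1)·avg)`, so windows are adjacent, disjoint, and reproducible.

## Element filters and disruption flags

Breakpoint-containing TADs (brTAD and flanking TADs) retrieve every
overlapping element regardless of biotype; `remaining` and explicit
regions keep only protein-coding genes, lincRNAs, lncRNAs, and other
elements with a tissue expression pattern. Flanking TADs use the
breakpoint-style (permissive) filter since they are requested precisely
to widen the search for candidates.

* **Gene disruption** requires the breakpoint strictly interior to the
  gene span; a breakpoint at an exact gene boundary counts as flanking.
  This is the conservative reading of an ambiguous edge case.
* **Loop disruption** requires the breakpoint strictly between the two
  anchors (`anchor_a.end ≤ pos < anchor_b.start`); anchor-internal breaks
  are ambiguous and not counted. `loops_total` counts loops with either
  anchor overlapping the gene span.
* **Cluster disruption** requires the breakpoint inside the cluster hull
  with at least one element entirely on each side — i.e. the break
  actually severs a regulator from its target; a break inside the only
  element, or outside the hull, does not qualify.

## Phenotype similarity

The ontology is a DAG with a single root; disease annotations propagate
upward so `ann(parent) ⊇ ann(child)` for every is_a edge. Information
content uses the natural log of the annotated-disease fraction,
`IC(t) = −ln(|ann(t)|/N)` — the Resnik convention; only ratios of scores
carry interpretive weight, so the log base is a free choice. Terms with
no propagated annotation have undefined IC and are dropped from queries
with a warning (an error only if nothing remains).

Set similarity is the **symmetric best-match average**
`½[meanₐ maxᵦ s(a,b) + meanᵦ maxₐ s(a,b)]` rather than the all-pairs
mean. The deciding property: self-comparison must equal the mean IC of
the set (this is what makes MaxSSc the ceiling of the scale), which holds
for best-match — when `a ∈ B`, `maxᵦ s(a,b) = s(a,a) = IC(a)` by the
`s ≤ min(IC)` bound — and fails for the all-pairs mean whenever the set
has more than one term.

The permutation p-value draws `n` (default 100) random term sets of the
query's size, uniformly without replacement, from the pool of terms with
at least one **direct** disease annotation — the terms that actually
appear in annotation files, hence the only ones a clinician could have
entered; propagated-only internal terms are excluded. A simulated score
equal to the observed score counts against significance (the comparison
is `≥`), making the p-value conservative. Each disorder gets its own
random stream derived from `(seed, disease_id)` via SHA-256, so results
are reproducible per disorder and independent of evaluation order.

## CNV database matching

Mutual overlap is `min(cov_query, cov_record)` in percent — equivalent to
requiring both coverages to pass the threshold (default 70%). Candidate
records must match the query's copy-number direction (loss vs gain);
benign evidence for a deletion says nothing about a duplication. Best-hit
ties break by higher record coverage, then lexicographically smaller
record id, purely for deterministic output. Frequencies are echoed from
the source, never imputed.

## Dosage rubric

Only machine-determinable criteria are automated:

| criterion | points | trigger |
|---|---|---|
| 1A | 0.00 | span contains protein-coding or functional elements |
| 1B | −0.60 | span contains none |
| 2A | +1.00 | established haploinsufficient (loss) / triplosensitive (gain) gene fully contained or disrupted |
| 2F | −1.00 | query completely contained in an established benign region |
| benign-overlap | −0.90 | best hit in any database is benign/likely-benign at 100% mutual overlap, and 2F does not apply |
| 3A/3B/3C | 0 / +0.45 / +0.90 | protein-coding gene count: loss bins 0–24 / 25–34 / ≥35, gain bins 0–34 / 35–49 / ≥50 |

Genes count toward section 3 when they overlap the span by ≥ 1 bp — the
simplest reproducible rule. Literature, de novo and inheritance criteria
cannot be derived from annotation files; they enter as manual adjustments
(`--manual-evidence id=points`) added to the sum. Scores are in
hundredths; banding uses inclusive edges (≥ 0.99 pathogenic, 0.90–0.98
likely pathogenic, −0.89–0.89 VUS, −0.98 – −0.90 likely benign, ≤ −0.99
benign), a total and monotone partition of the real line.

## Balanced-SV rule engine

Rules are evaluated in precedence order pathogenic → likely pathogenic →
likely benign → benign, first match wins, everything else VUS; a variant
matching both a benign-leaning and a pathogenic-leaning arm takes the
more pathogenic call (clinical conservatism). "Affected or encompassed"
means disrupted by a breakpoint or fully inside the SV span. The
position-effect arm fires for a gene with a dominant-disorder link inside
a breakpoint or flanking TAD whose cluster is severed or which has ≥ 1
disrupted loop, in a patient with significant phenotype overlap:
`PhenSSc/MaxSSc ≥ 0.5` and `p ≤ 0.05` by default, both configurable, plus
a `force_phenotype_overlap` expert override — borderline p-values on
small term sets are routinely overridden by expert judgement, so the gate
must be escapable without editing thresholds.

Sequencing triage keeps calls that exceed 1 kb, are novel or rarer than
1% in the curated databases, and touch a LoF-constrained gene
(oe < 0.35) or an AD-linked gene. Three-evaluator consensus takes the
majority call, else the median on the ordered five-level scale (the two
coincide whenever a majority exists, which the test suite verifies over
all 125 triples).

## Synthetic data generator

`make_toy_genome(out_dir, seed)` emits a two-chromosome universe: chr1
(600 kb, six 100-kb TADs) and chr2 (400 kb, four TADs); genes covering
the biotype and dosage-flag space; one regulatory cluster and four loops
around a planted intergenic breakpoint at chr1:150,000 (three loops and
the cluster straddle it); cytobands tiling both chromosomes; a CNV
database snapshot with planted and seeded-random records; and a
12-term/4-disease ontology whose closed forms anchor the similarity
tests (leaf ICs ln 2 and ln 4, branch MICA IC ln(4/3), self-similarity
(ln 2 + ln 4)/2 ≈ 1.0397, exact enumeration p = 1/6 for the two-term
query against its own disorder). Every planted truth is re-derived by
independent brute-force scans before the manifest is written, and
regeneration with the same seed is byte-identical.

`make_random_suite` stratifies random SVs of all five types across the
five outcome categories by construction and stores expected brTADs, best
hits and categories derived by linear scans — the oracle files the test
suite replays through the indexed implementation.

What the generator does **not** emulate: realistic TAD size
distributions, nested sub-TADs, the scale of the real phenotype ontology
(tens of thousands of terms), annotation noise, or genome-wide gene
density. Passing tests therefore demonstrate the correctness of the
rules and arithmetic on validated inputs, not calibration of thresholds
against real cohorts.

## Numerical choices and problem sizes

Oracle-equivalence suites use 1,000 random queries per comparison and the
permutation check uses n = 10,000 draws against the exact enumeration
value with a 3σ binomial tolerance; these sizes give tight checks while
keeping the default test run fast. Percentages in run summaries round to
one decimal (concordance, VUS share) and the VUS reduction to the
nearest integer, matching how such figures are conventionally reported.
Score arithmetic rounds to hundredths; float sums are rounded once, at
the end.

## Known limitations

* Complex SVs must be decomposed into simple SVs by the user.
* No VCF/BAM ingestion: variants enter via CLI arguments or the variant
  TSV; annotation enters via local TSV/OBO snapshots.
* The rubric automates dosage-content criteria only; breakpoint-in-gene
  LoF sub-criteria beyond the disruption flag, inheritance and literature
  evidence require manual adjustments.
* Tissue choice for the TAD reference is the user's: boundaries vary
  between tissues and no automatic selection is attempted.
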