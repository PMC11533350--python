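# Methods

## Scope and model

`magqc` classifies metagenome bins against the MIMAG quality tiers plus a
"near-complete" extension. It deliberately starts *downstream* of the heavy
estimators: completeness/contamination arrive as a CheckM-dialect table and
the rRNA/tRNA evidence as Bakta-style TSV or GFF3 annotations. The package
never invokes CheckM or Bakta and needs no databases; the software provenance
strings it writes into the metadata CSV are supplied by the caller.

Classification is a first-match rule cascade (see README for the table).
Properties that follow from the cascade and are enforced by tests:

* **Totality** — every valid (completeness ∈ [0,100], contamination ≥ 0,
  census) input gets exactly one category.
* **Monotonicity** — raising completeness never demotes a bin across the
  ordering Failed < {Low, Medium} < Near complete < High (Low/Medium is a
  completeness partition, not a ranking step); raising contamination never
  promotes; adding annotation features never demotes.

### Boundary conventions

The published bounds overlap or conflict at two points, resolved as follows:

* Medium/Low are "≤ 10%" contamination while Failed is "≥ 10%": at exactly
  10.0% the first-match order awards Medium (or Low), preserving every
  inclusive bound; only the doubly-claimed point is adjudicated.
* The near-complete tier is variously stated as "≤ 5%" and "< 5%"
  contamination; the tabulated inclusive bound wins, so exactly 5.0% is
  near-complete-eligible.
* Completeness for High/Near-complete is strictly greater than 90%: a bin at
  exactly 90.0% is Medium.
* Scores are compared exactly as parsed; no rounding policy is imposed on
  top of the (typically 2-decimal) input precision.

All five thresholds are configurable (`ClassificationThresholds`, surfaced as
`--hq-*`/`--mq-*` CLI options) but default to the standard, so default
behaviour is bit-identical to the published rules.

## RNA census

* tRNA coverage counts **distinct standard amino acids** with ≥ 1 non-pseudo
  tRNA whose product parses as `tRNA-<Aaa>`; duplicates collapse. The
  initiator fMet counts as Met (it charges methionine); selenocysteine,
  pyrrolysine and undetermined isotypes (`tRNA-Sec/Pyl/Xxx`) fall outside the
  20-amino-acid denominator. Unparseable products are skipped with a warning.
* rRNA presence is product-string based (`5S`/`16S`/`23S` tokens,
  case-insensitive) with a gene-name fallback (*rrf*/*rrs*/*rrl*). Pseudogenes
  never count.
* Partial rRNA genes: the standard asks for "presence and completeness" of
  these genes without operationalising completeness. The default is presence
  only; `min_len_fraction` (CLI `--min-rrna-len-fraction`, default 0)
  optionally requires a feature to span that fraction of a reference gene
  length (5S = 120 bp, 16S = 1500 bp, 23S = 2900 bp — typical prokaryotic
  full lengths, used only for this filter).

## Assembly statistics

N50 is the largest observed contig length L such that contigs of length ≥ L
cover at least half the total size — the common convention; a brute-force
enumeration over all candidate lengths serves as the test oracle. The
run-level binning summary sums bases/contigs over bins and divides by the
assembly totals; overlapping bins (legitimate when comparing competing
binners) are double-counted with a recorded warning rather than rejected, and
bin contigs absent from the assembly likewise warn but never abort.

## Input conventions

* Bin ids are filename stems; one recognised extension (`.fasta/.fna/.fa`,
  case-insensitive) is stripped, and quality-table ids are normalised the
  same way so the inputs join without a mapping file.
* Quality tables may be tab- or comma-separated (sniffed from the header);
  extra CheckM columns are ignored. Out-of-range scores, duplicate ids and
  non-numeric fields are hard errors naming the offending row.
* Annotations may be one file per bin (stem = bin id) or concatenated; in the
  concatenated case features are routed to bins by contig-id membership.
* Coordinates are 1-based inclusive everywhere (length = stop − start + 1);
  unknown strands are stored as `?`, never rejected — strand is irrelevant to
  the census.

## Reporting

The metadata CSV carries the MIMAG-recommended fields in a fixed column
order: quality tier, the two scores with their software provenance, 16S
recovery, tRNA coverage as `N/20`, the "Marker gene" completeness approach,
and the assembly statistics. 5S/23S recovery flags are appended as trailing
columns — without them the CSV could not audit the high-quality rule.
Writing then re-reading a CSV reproduces every field exactly.

Each run writes a JSON sidecar (`<prefix>.magqc.json`, schema field
`magqc_schema: 1`). The HTML report is rebuilt purely from the sidecars found
in the output directory, which is what makes cross-run comparison work: any
number of runs placed in one directory are summarised side by side. Report
bytes are a deterministic function of the runs and the package version —
figures are matplotlib SVG with a fixed hash salt and no date metadata, and
no network assets are referenced.

## Synthetic data generator

The fixture module fabricates all four inputs: random A/C/G/T contigs for
bins and assembly (plus a configurable fraction of unbinned contigs, default
0.25 of the bin contig count), a quality table with *injected* completeness/
contamination, and per-bin annotation TSVs containing exactly the requested
number of distinct tRNA amino acids and the requested rRNA genes at reference
length. Each bin spec is validated at construction: the requested scores and
census must actually classify to the declared target category, so fixture
ground truth is consistent by construction. Generation is deterministic —
identical spec + seed gives byte-identical files.

What the generator does **not** emulate: real marker-gene structure (scores
are injected, not estimated), biological sequence composition, fragmented or
partial RNA genes, annotation noise, or any correlation between contig
lengths and quality. End-to-end tests on fixtures therefore demonstrate that
parsing, bookkeeping and classification are correct — not that upstream
estimates on real data are accurate.

## Problem sizes and numerical choices

The test suite runs at desk scale: classifier fuzzing uses 10,000 random
score/census triples against an independently stated predicate oracle; the
N50 oracle check uses 1,000 random length multisets; the end-to-end round
trip classifies 100 random single-bin fixtures (20 per category) through the
full file-level pipeline; fixture contigs are 0.3–4 kb so a whole dataset is
a few tens of kilobases. Acceptance sweeps use 0.1% grids over completeness
(0–100) and contamination (0–20 or 0–30) and the integer tRNA grid 0–20.
Grid values are generated as integers divided by 10, so boundary points like
5.0 and 10.0 are exact binary comparisons, not accumulated floating-point
sums.

## Known limitations

* Only the tab/comma `checkm qa` table dialect is parsed, not CheckM's
  fixed-width pretty-printed stdout; GenBank/EMBL annotations are not read.
* Contamination-weighted composite scores (e.g. completeness − 5 ×
  contamination) and CheckM2-style model-based estimates are out of scope.
* Eukaryotic MAGs (18S/28S) are not handled; the census is prokaryotic.
* The HTML report is static; it favours reproducible bytes over
  interactivity.
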