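# Methods

## The extraction model

`synoptex` treats structured extraction from synoptic pathology text as a
per-field matching task against a closed ontology. A report is first cut
into heading-anchored segments; for each (segment, field) pair a
deterministic prompt is rendered; a backend maps the prompt to a raw
response; the response is parsed and validated against the field's allowed
values. The unit of output is one `ExtractionRecord` per (report, field):
a canonical option string, free text, or an explicit abstention, plus an
optional integer "extra" channel for numeric-template fields, the raw
response, and a status (`ok` / `repaired` / `invalid`).

Assumptions baked into this model:

* the report is label-prefixed checklist text — headings of the form
  `"Label:"` at line starts delimit the relevant content;
* each field's answer, when present, is expressible as one of its canonical
  options (or a synonym surface form), or as a numeric template plus an
  integer;
* abstention is a legitimate value, distinct from a parse failure.

## Ontology

Three levels: 8 fixed sections (specimen, tumor, margins, regional lymph
nodes, distant metastasis, pTNM classification, additional findings,
comments), 86 subsections, 229 fields. The bundled inventory is
representative of CAP breast protocols (DCIS, invasive biopsy/resection and
Phyllodes content); the cardinalities are fixed, the field names are the
package's own. Value kinds:

* `categorical` — ≥2 canonical options, optional synonyms
  (e.g. "IDC" → "Invasive ductal carcinoma");
* `numeric_template` — a display template with exactly one placeholder
  em-dash (`"Exact distance: — mm"`); ASCII `-` is accepted on read and
  canonicalized. The number travels separately as the integer extra;
* `free_text` — no options.

Schemas are CSV (UTF-8, comma-delimited, header
`section,subsection,field_id,label,value_kind,options,numeric_template,synonyms`,
options and synonyms pipe-delimited within a cell). Loading is order-stable
and validated; the schema version is a content hash recorded in run
manifests for traceability. The bundled CSVs were checked, at build time of
the bundle, for a property the synthetic generator depends on: no option's
normalized surface form occurs inside its own subsection heading or inside
the generator's noise scaffolds, so heading text alone can never make a
negative case positive.

## Normalization ("exact match")

All matching and scoring compares normalized forms: trim, collapse internal
whitespace, casefold, unify Unicode dash variants to `-`. Numeric templates
additionally drop their placeholder before matching, so
`"Exact distance: — mm"` matches report text `"Exact distance: mm"`. A
true positive requires the normalized value to equal the normalized truth
and, when the truth carries an extra, the integers to agree (configurable
off via `require_extra_match=False`).

## Segmentation

One regex pattern per subsection heading, auto-derived from the schema
(`^label:`, case-insensitive, multiline), with an override table for
irregular headings and an optional section-level granularity. All matches
of all patterns jointly tile the labeled region: each segment runs from its
match to the next match of any pattern or end of text, so segments never
overlap and spans (0-based, half-open) anchor losslessly into the source.
Repeated headings produce one segment per occurrence; noise tokens such as
`"nan"` are retained — filtering is the extractor's concern.

## Oracle backend and error injection

The reference backend is a rule-based matcher: it selects the **longest**
allowed option (or synonym) whose normalized form occurs in the segment,
breaking length ties by schema order, captures `"Found number N"` into the
extra channel for numeric fields, and abstains otherwise. It exists so the
whole pipeline is testable offline with a known end-to-end identity:
on non-adversarial synthetic cases its sensitivity and specificity are
exactly 1.0.

`oracle-noisy` wraps it with seeded corruption at rates
(`eps_swap`, `eps_drop`, `eps_spurious`): a present value is replaced by a
uniformly chosen wrong option with probability `eps_swap` or forced to
abstain with `eps_drop`; an abstention becomes a spurious option with
`eps_spurious`. Expected sensitivity is `1 − eps_swap − eps_drop` and
expected specificity `1 − eps_spurious`, which gives the evaluation engine
a quantitative recovery check (realized values within 3 binomial standard
errors in the shipped tests). Per-call seeds are derived from the backend
seed and a call counter, so a fixed run order is byte-reproducible.

Response parsing is bounded: strict JSON first, then exactly one repair
pass (strip code fences and prose, take the first decodable JSON object),
then `invalid` with the raw response retained. Invalid records are treated
as non-extractions by the evaluator.

## Synthetic validation corpus

The generator emulates the surface styles of checklist free text, not whole
documents. Default composition: **864 cases = 445 positive + 419
negative**, spread round-robin over a seeded shuffle of all categorical and
numeric-template fields. Styles:

* positive — `"Label: value"`, the same with a trailing `"nan"` noise
  token, and numeric-template text with a `"Found number N"` tail
  (N drawn uniformly from 1–20);
* negative — heading plus distractor prose
  (`"Comment(s):. nan. Some other free text."`) or bare noise
  (`"Label: nan."`);
* adversarial (flagged) — ambiguous phrasing that defeats literal matching:
  numeric tails under a mislabeled vague heading
  (`"Label (Note B): At least:. nan. Found number N"`) and vague
  `"Tumor is malignant"` text with no canonical option. The default
  adversarial fraction is 0.05 per polarity (43 of 864 cases), a package
  choice: large enough to exercise the flagging path, small enough that the
  non-adversarial identity property still covers ~95% of the suite.

Every non-adversarial case's polarity is verified at generation time
(positives by the matcher itself, negatives by an option-surface scan) and
re-verified in the tests by an independent exhaustive substring scan.
Ground truth is written to a manifest separate from the input texts.

What passing on this corpus does **not** show: robustness to abbreviation
variety, negation and uncertainty phrasing, cross-field context, OCR noise,
or institution-specific formatting — exactly the phenomena behind the gap
between synthetic and real-world performance. The harness is built to
measure that gap once positive-only clinical annotations are supplied; it
cannot manufacture them.

## Evaluation

Complete regime: TP on normalized exact match (value + extra), FN when a
present truth is missed or mismatched, TN when an absent truth meets an
abstention (or invalid response), FP when an absent truth meets a
prediction. Positive-only regime: truth records never assert absence, so
FP/TN are structurally unavailable; predictions for unannotated fields are
skipped, and the engine refuses to compute precision, specificity, F1 or
MCC — only recall = TP/(TP+FN). Zero-denominator metrics are reported as
unavailable, never as zeros. Percentages render half-up to 1 decimal
(machine output keeps raw proportions); the reality gap is synthetic
accuracy minus real recall in percentage points on the rendered scale.

## Design choices where the design was open

* **Segments carry all fields of their subsection** (`field_ids` tuple)
  rather than a single field id; segmentation granularity (subsection vs
  section) is configurable, defaulting to subsection.
* **Field multiplicity**: a field is attempted against every segment of its
  subsection in document order; the first non-abstaining result wins.
* **Fields attempted per report**: an explicit field list, defaulting to
  all 229 fields; field-targeted runs (synthetic cases) pass a one-field
  list per document. The bundled schema does not partition fields by report
  type, since no authoritative partition exists.
* **"Parallel initialization"** (ontology load, segmentation) is treated
  as a dependency statement, not a concurrency mandate: the stages are
  independent and run sequentially for determinism.
* **Templates are data**: prompt wording ships as versioned text assets
  (`default-v1`, `freetext-v1`), addressed by id, with a hard length
  ceiling (20 000 chars) that errors rather than truncates.

## Numerical and degenerate-input conventions

Longest-match ties break toward schema order; empty or whitespace-only
documents are an error for segmentation, while a report with no matching
heading yields an empty segment list and flagged abstentions downstream;
error-injection rates must lie in [0, 1] with swap + drop ≤ 1; all derived
seeds stay below 2³¹; rounding is decimal half-up.

## Problem sizes

The shipped tests and the acceptance script run the full default corpus
(864 field-targeted cases, one pipeline pass per case, plus three
error-injection passes); a complete run takes a few seconds on one CPU.

## Known limitations

* The bundled field inventory is representative, not an authoritative CAP
  transcription; real deployments should load their own schema CSVs.
* The oracle backend is a literal matcher; it is a testing instrument, not
  a clinical extractor, and adversarial cases are designed to defeat it.
* Live-provider adapters are stubs: unmaintained network plumbing kept
  outside the tested surface.
* Free-text fields are extracted verbatim and never scored for semantic
  equivalence.
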