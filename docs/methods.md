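# Methods

## Validation model

`registryqc` treats registry validation as a four-phase streaming pipeline
over a delimited text file whose layout is declared by a *protocol*:

1. **Pre-record cycle.** Structural screening: an empty or too-small
   dataset (default minimum one record), a header that does not match the
   protocol's variable names, and rows with the wrong column count produce
   critical (`C-`) messages. Criticals are run-level: by default any
   structural finding aborts the run (`on_structural_error="abort"`);
   in `continue` mode malformed rows are skipped and reported while the
   rest of the file is validated. Perfect duplicates — repeated
   (patient ID, tumour ID) keys — are also detected here with a hash-set
   whose memory grows with the number of distinct keys only; duplicate
   detection reports but never aborts.

2. **Record cycle.** Records are parsed and checked one at a time.
   Univariate checks classify each field as empty, coded-unknown,
   format-broken, out of range, or usable. Multivariate checks
   (topography×morphology, age×tumour type, TNM×stage, basis of
   diagnosis×morphology, date order) run only on fields classified usable:
   a field that already failed format or range emits its single `E-FORM`/
   `E-OUTR` and is excluded from downstream rules, so one typo cannot fan
   out into a cascade of spurious warnings. For each cross-record rule the
   record's messages are intersected with the rule's *acceptance criteria*
   — a configured set of (variable, code) pairs deemed critical for that
   rule. Accepted records are appended to the rule's temp file
   (`qcs_acceptable_by_rule_<id>.csv`) as `line_no;field;...;field`, so
   later findings can be re-anchored to the original order. A missing year
   of incidence blocks the MPT rule; a missing stage does not.

3. **Sorting.** Each rule's temp file is sorted by its key (patient ID for
   MPT) with an external merge sort: chunks of at most `chunk_size`
   records (default 50 000) are sorted in memory and merged with a k-way
   heap, so peak memory is bounded by the chunk, not the file. The sort is
   stable with ties broken by original line number, making batch order
   within a patient reproducible. Output keeps the reference naming
   convention (`...-by-PAT.csv`).

4. **Post-record cycle.** Sorted files are read one patient batch at a
   time (a decreasing key raises an internal error). The MPT rule first
   filters the batch by behaviour: only tumours with behaviour digit ≥ the
   configured floor (default 3, malignant) are evaluated, so a benign
   breast record is ignored. Every unordered pair with distinct tumour IDs
   receives a verdict: *same primary* when the topography site groups
   match **and** the morphology families match, *independent* otherwise,
   *not evaluable* when a code is absent from the grouping tables. Each
   same-primary pair yields one `W-MULP` warning anchored to the later
   record; clusters (transitive closure over pairwise verdicts, covering
   the "twice or more" case) are counted for the run summary. The date of
   incidence is carried for reporting but never affects verdicts, in line
   with the site/histology-based multiple-primary philosophy.

Finally all messages are re-sorted by original line number (ties by code)
and written to a semicolon-delimited CSV (one message per row, columns
`Line;Pat;Tum;BoD;Topo;Morpho;Beh;Sex;DoI;DoB;Var_Name;Var_Value;
Error_Code;Severity;Detail`; multi-variable names/values joined with `|`
so the file round-trips exactly) and a TXT report (header block with run
metadata and criticals, code legend, per-code record-count summary,
detail). Severity is derivable from the code prefix: `W-` warning, `E-`
error, `C-` critical. The summary counts *records* per code, not messages,
so two range errors in one record count once. A configurable message cap
(default 10 million) aborts pathological runs with `C-CAP`.

## TNM/stage check

Complete clinical and pathological triples are checked independently. T/N/M
values are reduced to their main category (`1biv` → `1`, `2a` → `2`); the
stage lookup is first-match over the (edition, site group) rows of the
stage-grouping table, where T and N may be wildcards but M is always
explicit so the invariant *M1 ⇒ stage IV* can be enforced at load time.
Recorded and implied stages are compared on the roman-numeral stage group
only (I/II/III/IV), because sub-stage letters shift between editions while
the group does not; an M1 triple with a non-IV stage always warns, even
for sites without a bundled grouping. Sites or editions absent from the
table are counted as *not evaluable* (reported in `RunResult`), not
warned. The site group of a record is derived from the 3-character
topography prefix via the topography-group table.

## Age at diagnosis

Completed years from date of birth to date of incidence when both parse;
otherwise the explicit `Age` column. Negative ages make the age checks
inapplicable (the date-order check flags the record instead).

## Configuration and reference tables

All protocol layouts and check logic data live in plain-text config files
(YAML protocols, semicolon-CSV tables with a header row), so the behaviour
of most checks can be changed without code changes; overrides replace a
bundled table wholesale and are validated against the same invariants
(topography/morphology pairs must reference valid codes, M1 rows must map
to IV, family/group tables must be total over the code sets).

The bundled tables are deliberately small curated subsets — a few hundred
topography/morphology codes and pairs, four unlikely age combinations,
stage groupings for breast, colorectal, lung and prostate (7th edition),
one morphology-family and one site-group partition. They are large enough
to exercise every rule and every worked example; they are **not** the
official ICD-O-3 / TNM / multiple-primary coding tables, which registries
should supply as overrides. The 56- and 39-variable incidence layouts keep
the published variable counts by combining 22 semantically active
variables (identifiers, demographics, tumour coding, TNM/stage, follow-up)
with named treatment/registry placeholder columns that are format-checked
only.

## Synthetic data generator

The generator emulates a pseudonymised registry extract for test purposes:
opaque zero-padded patient/tumour IDs; (topography, morphology) drawn
jointly from the allowed-pair table (never producing accidental `W-MOTO`);
behaviour fixed at 3; ages 0–84 rejection-sampled against the unlikely
table; sex kept coherent with sex-specific sites; diagnosis dates
2016–2019 with birth dates back-computed from age; basis of diagnosis kept
microscopic whenever the morphology is in the specificity table; TNM and
stage generated through the same grouping lookup the validator uses
(sites without a grouping get stage `X` and empty TNM). By default 10% of
records belong to two-tumour patients whose tumours are sampled to be
*independent* (different site group and family), so a clean file carries
multi-tumour structure yet validates with zero messages.

Error injection mutates singleton-patient records only, one record per
planned defect, each defect chosen to trigger exactly one message
(e.g. `E-OUTR` sets sex to 5; `W-TNMS` plants the breast pT3 pN1 pM1 /
stage IIIA configuration; `E-DUPL` appends a copy of a clean record;
`W-MULP` appends a same-group/same-family second tumour for a patient).
The ledger written beside the file records every (code, line, variable)
slot, and the package's central property — asserted across randomised
profiles and seeds — is that engine output equals the ledger exactly.
Everything is driven by one `random.Random(seed)`, so generation is
byte-deterministic.

What passing these tests shows: the engine finds exactly the defects that
are present, in the right places, with no false positives on clean data
*under the bundled tables*. What they do not show: coverage of the full
official code sets, real-world coding dialects, haematological
multiple-primary timing/transformation rules (out of scope; the family
table may include lymphohaematopoietic families but no timing logic), or
epidemiologically realistic site/age mixes — the generator targets check
coverage, not realism.

## Numerical and design choices

- Dates are strict ISO `YYYY-MM-DD`; anything else is `E-FORM`.
- Topography is canonicalised to the undotted uppercase form (`C61.9` →
  `C619`) for every table lookup; reports show the raw input value. The
  converter's `normalize_topography` fixup additionally completes
  3-character codes with the `.9` unspecified-subsite digit.
- Coded unknowns (sex 9, stage X/9) are in-range and not "missing"; they
  simply make the checks that need the value inapplicable.
- The behaviour domain is {0,1,2,3}, so an unknown behaviour is an
  `E-OUTR` that the MPT acceptance criteria treat as critical; the
  post-record behaviour filter is then a plain `beh >= floor` comparison.
- Test and acceptance runs use files of 30–1000 records with small sort
  chunks (2–100) to exercise the multi-chunk merge path; these sizes keep
  the full suite in seconds while covering every phase boundary.

## Known limitations

- Bundled reference tables are working subsets, not official publications.
- No haematological MPT rules, no treatment-variable plausibility checks,
  no cross-file (incidence vs population) reconciliation.
- PDF report rendering is not implemented (CSV and TXT carry the full
  content); no GUI, no parallel execution, no duplicate merging.
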