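# registryqc

Quality-check engine for population-based cancer registry (PBCR) data
files, with a companion layout converter and a synthetic-data generator.

Cancer registries collect one row per registered tumour — patient and
tumour identifiers, demographics, ICD-O-3 topography/morphology/behaviour,
basis of diagnosis, TNM and stage, follow-up — plus aggregate mortality,
population and life-table files. Before such files can feed incidence or
survival statistics, they must be screened for impossible or unlikely
codes and code combinations. `registryqc` performs that screening the way
registry-grade validation tools do:

- **univariate checks** — required values present (`E-MISS`), parseable
  (`E-FORM`) and within the protocol's allowed range (`E-OUTR`), e.g. sex
  must be one of 1/2/3/9, topography must be a real ICD-O-3 code;
- **within-record consistency checks** — topography × morphology against a
  table of allowed combinations (`W-MOTO`), unlikely age × tumour-type
  combinations such as retinoblastoma in adults (`W-AGMT`), TNM versus
  stage group via edition- and site-specific stage grouping tables, where
  any M1 must be stage IV (`W-TNMS`), morphology too specific for a
  non-microscopic basis of diagnosis (`W-BDMO`), date coherence (`E-DATE`);
- **cross-record checks** — perfect duplicates, i.e. repeated
  (patient, tumour) keys (`E-DUPL`), and multiple-primary-tumour (MPT)
  detection: two records of one patient are flagged as the *same primary*
  (`W-MULP`) when their topography codes share a site group **and** their
  morphology codes share a family.

The engine streams: it keeps one record in memory during the record cycle,
writes per-rule temp files of acceptable records
(`qcs_acceptable_by_rule_MPT.csv`), external-sorts them by patient ID
(`...-by-PAT.csv`) with bounded chunks, and processes one patient batch at
a time in the post-record cycle. Findings are re-sorted to the original
dataset order and written as a semicolon-delimited CSV report plus a TXT
report with run metadata, the code legend and a per-code record-count
summary.

Everything configurable lives in plain-text files: ten protocol layouts
(incidence/mortality/population/life-table in their 2014 and 2020
versions, with 56/39/5/5/5/4/6/6/4/6 variables), and reference tables for
valid codes, allowed topography×morphology pairs, unlikely age
combinations, TNM value sets (including legacy notations such as pN
`1biv`), stage groupings, morphology families and topography site groups.
The bundled tables are curated working subsets sufficient for testing and
demonstration; registries can override any table wholesale with their
official versions (`load_reference_tables(table_overrides=...)`).

## Worked example

Generate a synthetic 30-record incidence file with two out-of-range values
and one same-primary pair injected, then validate it:

```bash
$ printf 'E-OUTR: 2\nW-MULP: 1\n' > profile.yaml
$ qcs generate --protocol incidence-2020 --n 30 --seed 4 \
      --errors profile.yaml --output gen
data file : gen/incidence.csv
ledger    : gen/incidence.ledger.csv
  E-OUTR  2
  W-MULP  1
$ qcs validate --protocol incidence-2020 --input gen/incidence.csv --output out
records processed : 31
messages          : 3
  E-OUTR  2
  W-MULP  1
csv report: out/qcs_report.csv
txt report: out/qcs_report.txt
log report: out/tmp/qcs_rule_output.csv
$ echo $?
1
```

The file holds 31 records (30 base records plus the appended second tumour
of the MPT pair). The two `E-OUTR` errors are the injected out-of-range
sex values; the `W-MULP` warning flags the patient whose two tumours share
a site group and morphology family — exactly the generator's ledger, which
is the package's central correctness property. Exit code 1 means findings
(0 = clean, 2 = blocking structural failure, e.g. an empty file or a
header that does not match the protocol).

The same pipeline is available as a library:

```python
import registryqc as q

result = q.run_validation("gen/incidence.csv", "incidence-2020",
                          output_dir="out")
print(result.messages_by_code)   # {'E-OUTR': 2, 'W-MULP': 1}
```

Near-miss extracts (shuffled columns, local codings such as sex `M`/`F`,
3-character topography like `C61` for `C61.9`) are made protocol-compliant
with `qcs convert --mapping map.yaml --protocol incidence-2020 ...`.

## Configuration layout

```
configs/
  protocols/<id>.yaml     # delimiter, ordered variables (name, position,
                          # datatype, allowed set/range/pattern/table,
                          # missing codes, required), rules, per-rule
                          # acceptance criteria (variable, code pairs)
  tables/*.csv            # semicolon-delimited with a header row
  tables/checks.yaml      # non-microscopic BoD codes, MPT behaviour floor
```
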