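# paleoaudit

Compliance auditing of publicly archived ancient-genomics sequencing data.

Ancient-DNA studies rely on destructive sampling of finite material, yet the
data they deposit in the INSDC archives (ENA/SRA/DDBJ, with BioProject and
BioSample) is frequently incomplete: only reads that aligned to a reference
are archived, BAM files are hard filtered on mapping quality or read length,
read-group `SM`/`LB` identifiers do not match the archive metadata, sample
records lack geography, dating or tissue information, and data from
screening-negative samples is silently dropped. `paleoaudit` turns the
corresponding best-practice expectations into an executable rubric for data
producers (pre-submission linting), reviewers and data curators (systematic
surveys).

## What it does

* **Study model** (`archive_model`) — an offline `StudyBundle` mirroring the
  archive hierarchy (study → samples → runs → analysis files), with a
  canonical JSON serialisation and adapters for ENA filereport TSVs and
  BioSample attribute dumps read from local disk.
* **File inspection** (`seqcheck`) — deterministic per-file statistics over
  the first *N* records of each FASTQ/BAM: MAPQ and length histograms,
  unmapped fraction, 3′ adapter-residue fraction (suffix-vs-adapter-prefix
  matching with a mismatch budget of ⌊0.1·overlap⌋), read-group roster, and
  an internal BAM validation rule set (V1–V7). Hard-filter signatures are
  inferred from distribution floors: a file whose mapped reads all sit at
  MAPQ ≥ 25, or whose reads are all ≥ 30 nt, is read as hard filtered —
  provided enough reads were seen (`min_confident_n`).
* **Metadata audits** (`metadata_audit`, `crosscheck`) — completeness of
  sample metadata (geography / dating / tissue / specimen voucher, each
  split into *any information* vs *dedicated field*; coordinate parsing;
  radiocarbon lab-code detection) and cross-record consistency (read-group
  `SM`/`LB` against archive sample aliases and library names, duplicate
  sample registrations, archived-vs-declared sample counts).
* **Rubric and aggregation** (`criteria`, `cohort`) — 32 criteria across
  five thematic tables, each with explicit applicability (criteria whose
  inputs are missing are *indeterminate*, not failed, and leave the
  denominator); per-criterion cohort counts and survey-style tables with
  half-up percentage rounding.
* **Synthetic studies** (`synthetic_data`, `planted`) — a seeded generator
  of complete study bundles (metadata + FASTQ/BAM on disk) with planted
  violation profiles covering every criterion, plus cohort builders that
  plant published survey marginals; the ground truth for all end-to-end
  testing.

## Worked example

Generate a synthetic study whose BAM files were hard filtered at MAPQ 30
and whose samples carry no geographic metadata, then audit it:

```sh
$ python - <<'EOF'
import json, pathlib
spec = {"seed": 7, "reads_per_file": 5000, "samples_per_study": 3,
        "entries": [{"n_studies": 1, "violations": ["mapq_filter(30)", "no_geo"]}]}
pathlib.Path("spec.json").write_text(json.dumps(spec))
EOF
$ paleoaudit generate spec.json cohort
generated 1 studies under cohort (manifest: cohort/manifest.tsv)
$ paleoaudit audit cohort/SYN0001/bundle.json --format tsv --out report.tsv
$ echo $?
1
```

Exit status 1 means at least one applicable criterion failed. The report
shows exactly which (criterion, applicable, passed):

```
no_any_hardfilter   true   false
no_mapq_hardfilter  true   false
geo_any             true   false
```

`no_mapq_hardfilter` failed because the minimum MAPQ among thousands of
sampled mapped reads is 30 — an unfiltered ancient-DNA alignment file
always contains multi-mapping (MAPQ 0) reads — and `no_any_hardfilter` is
its composite. `geo_any` failed because no sample attribute or free-text
field contains geographic information. The preflight view groups the same
findings by submission step:

```
$ paleoaudit lint cohort/SYN0001/bundle.json
[ok           ] step1: Register samples (reuse existing accessions; archive negatives)
[ACTION NEEDED] step2: Provide informative sample metadata
    - geo_any: FAIL
...
[ACTION NEEDED] step6: Prepare read alignments (no hard filters, correct read groups, validated)
    - no_any_hardfilter: FAIL
    - no_mapq_hardfilter: FAIL
[ok           ] step7: Deposit read alignments as analysis files
```

Real archived studies are audited the same way after converting an ENA
filereport and BioSample dump with
`paleoaudit.archive_model.from_ena_filereport` and downloading the
referenced files.

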