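# Methods

## The audit model

`paleoaudit` treats an archived study as a linked bundle of records —
study, samples, sequencing runs, analysis files — plus the data files those
records reference, and optionally a "paper report" of author-declared facts
(number of samples analysed, number studied in total, capture usage,
previously published samples). Every criterion is a predicate over this
bundle with an explicit *applicability* condition, producing one of three
outcomes: pass, fail, or indeterminate/not-applicable. Indeterminate is
never treated as failure; it removes the study from that criterion's cohort
denominator. This mirrors how survey tables over heterogeneous studies are
actually tabulated: adapter trimming can only be judged for studies that
archived raw reads, read-group criteria only for studies that archived
alignments, SM-matching only where SM tags exist at all.

Study-level verdicts for per-sample metadata criteria use *any-sample*
semantics: a study "has geographic information" if at least one sample
does. The per-sample breakdown is retained as evidence. Every failing
verdict carries evidence naming the tag, file or value that decided it.

## File inspection

Statistics are computed over the **first N records** (default N = 10 000)
of each file, not a random sample. This keeps the auditor deterministic and
streaming, and matches the convention of surveying the first listed file of
each study. FASTQ files (plain or gzip) contribute length and adapter
statistics and count entirely as unmapped; BAM/CRAM files additionally
contribute MAPQ histograms, unmapped fractions and read-group rosters
(via pysam). A BAM containing no mapped reads is treated as equivalent to
FASTQ — raw reads in BAM clothing.

**Adapter residue.** A read carries adapter residue when some suffix of it
matches a prefix of a known adapter with overlap ≥ 8 and at most
⌊0.1 · overlap⌋ mismatches (non-nucleotide symbols count as mismatches; the
reported hit is the leftmost, i.e. longest, such suffix). The shipped
adapter set is Illumina TruSeq R1/R2 and Nextera, replaceable by any FASTA.
A file counts as untrimmed when more than 1% of sampled reads match
(`adapter_threshold = 0.01`); genuinely adapter-free random sequence
produces chance matches at a rate orders of magnitude below this. The
per-file fraction is computed by a vectorised matcher proven equivalent to
the scalar definition by an exhaustive-scan oracle in the test suite.

**Hard-filter inference.** Archived alignment files rarely document their
filtering, so filtering is inferred from distribution floors:

* MAPQ-filtered ⇔ ≥ `min_confident_n` mapped reads were seen and the
  minimum MAPQ among them (excluding 255 = unavailable) is ≥
  `mapq_trigger` (default 25);
* length-filtered ⇔ ≥ `min_confident_n` reads were seen and the minimum
  read length is ≥ `length_trigger` (default 30);
* unmapped-removed ⇔ a BAM with mapped reads contains zero unmapped
  records.

The triggers reflect where ancient-DNA alignment files are commonly cut
(MAPQ 25–30, length 30–35); an unfiltered file essentially always contains
MAPQ-0 (multi-mapping) reads and sub-30-nt fragments, so observed floors at
or above the triggers are strong evidence of irreversible read removal.
`min_confident_n` (default 1000) guards against small files hitting floors
by chance; below it the criterion is indeterminate rather than decided.
The "any hard filtering" composite is defined as MAPQ-or-length only;
duplicate-read removal is deliberately not inferred (absence of
duplicate-flagged reads is uninformative), and removal of unmapped reads is
not a filtering criterion by itself since it is legitimate when raw reads
are archived separately.

**BAM validation** uses a fixed internal rule set rather than an external
tool: V1 header declares a format version; V2 read-group IDs unique; V3
every record's RG tag resolves to a declared read group; V4 mapped records
lie within contig bounds; V5 sequence/quality lengths agree; V6 unpaired
records carry no mate/pairing flag bits; V7 records follow the declared
sort order (unmapped-last convention for coordinate order). Full parity
with external validators is a non-goal; the rules cover the record-level
defects the rubric needs.

## Metadata detection

Detection is lexicon-driven and configurable (YAML). Dedicated-field lists
default to the tags archives actually display (e.g. *geographic location
(region and locality)*, *date* / *collection date*, *tissue* /
*organism part*, *specimen voucher* / *biological material*); attribute
tags are matched case-insensitively but stored verbatim. "Any information"
additionally scans free-text fields (Description-like tags and the sample
title) with a flat gazetteer of place names, a tissue term list, date
patterns (numbers followed by BP / cal BP / BCE / BC / CE / AD / ka), and
radiocarbon lab-code prefixes (OxA, Beta, Poz, KIA, …; prefix + optional
separator + 1–6 digits, case-sensitive). Coordinates accept signed decimal
degrees and sexagesimal D-M-S with hemisphere letters, and are
range-checked.

This is exact matching, not named-entity recognition. The synthetic
generator plants only vocabulary from the shipped lexicons, which makes
detection exact on fixtures; recall on arbitrary real-world free text is
explicitly not guaranteed, and passing tests demonstrate correctness of the
audit logic, not real-world NER performance.

**Identifier matching** (read-group SM vs sample alias/accession/title, LB
vs library names) is exact-after-whitespace-trim by default, with an
optional case-insensitive mode — automated reuse depends on machine-exact
identifiers. Duplicate sample registrations are detected by alias
normalisation: casefold, separator unification, and stripping of trailing
duplicate-marker tokens ({new, ss, capture, repeat, rerun, v2},
configurable). Bare trailing digits are never stripped — S1 vs S2 are
distinct samples, not duplicates. This heuristic is validated only on
planted fixtures; identifying true duplicates in the wild additionally
requires reading the papers.

## The synthetic generator

The generator emulates exactly the properties the auditor inspects, and
nothing else. Reads are uniform A/C/G/T with triangular fragment lengths
(min 25, mode 45, max 120 nt) — the short-fragment regime of ancient DNA.
Synthetic BAMs are fabricated directly against a toy two-contig reference
(2 × 50 kb, uniform positions); no aligner is run. The baseline unmapped
fraction is 0.7 (typical low-endogenous material), and mapped reads draw
MAPQ from a fixed mixture over {0, 20, 25, 30, 37, 60} with weights
(.08, .08, .09, .25, .25, .25): enough mass at 0 and 20 that unfiltered
files are never mistaken for filtered ones, and enough mass at ≥ 30 that a
planted MAPQ ≥ 30 filter leaves a confidently-sized mapped sample at the
default 5000 reads/file. Whenever a MAPQ (length) filter is *not* planted,
the generator additionally guarantees one kept mapped read with MAPQ 0
(length 26 nt): an unfiltered file of any size contains such reads, and the
guarantee makes the baseline's unfiltered appearance independent of
sampling luck in small files. No damage patterns, PCR duplicates,
contamination or biological signal are simulated — all are irrelevant to
the criteria and non-goals of the generator.

Each violation code inverts exactly one criterion: appending ≥ 10 nt of
adapter to 40% of reads (untrimmed adapters), dropping mapped records below
a MAPQ/length threshold, stripping unmapped records, removing or mangling
read groups, registering alignments as runs, registering a suffixed
duplicate sample with its own library, omitting metadata fields or moving
them into free text, declaring studied samples whose data is never
archived, and so on. A shipped entailment table records which additional
criteria each code *logically* drags along (composites, applicability
changes); the round-trip identity — `audit(generate(profile))` fails
exactly the planted criteria and their entailments — is asserted for every
code at 1000 and 10 000 reads/file. Two profile switches select study
designs rather than defects: `archive_alignments=False` (raw-only studies)
and `used_capture` (capture studies), needed to realise joint table
splits. An aligned-only study necessarily registers its BAMs as primary
run records with unmapped reads stripped; its entailed failures therefore
include the analysis-file criterion.

Determinism: per-study seeds derive from the cohort seed plus study index;
per-sample streams use spawned sub-sequences. FASTQ output is
byte-identical across runs; BAM record streams are identical (BGZF
container bytes are not compared).

## Planted survey cohorts

`fixtures/table*.json` transcribe published per-criterion marginal counts
from a 42-study survey of ancient-genomics archiving practice (e.g. 20/42
archived raw reads, 2/33 used analysis-file registration, 3/25
geography-bearing studies provided coordinates). The builders in
`paleoaudit.planted` convert these marginals into cohort specs — one
criterion family per cohort, since the true joint per-study profile across
all criteria is not public — and `scripts/acceptance.py` regenerates,
audits and aggregates each cohort, recovering the printed percentages end
to end. The script runs at the generator's default scale (5000 reads/file,
3 samples/study, 42-study cohorts); the in-suite acceptance tests run the
same pipeline at 2000 reads/file with the confidence floor scaled to 300
so the whole suite stays fast.

## Numerical and design choices

* Percentages are rounded **half-up** to one decimal (not banker's
  rounding), verified against all sixty printed table percentages by an
  independent integer-arithmetic recomputation; rendering drops a trailing
  ".0" (45% not 45.0%).
* Aggregation refuses to mix verdicts with different configuration
  fingerprints (SHA-256 digest of the full config including lexicons).
* `sample_count_match`, `total_reported` and `all_samples_archived` are
  indeterminate when the bundle has no paper report — the auditor cannot
  count what the paper declared.
* `all_samples_archived` uses ≥ (not =) against the declared studied
  total, so library-level over-registration is caught by
  `sample_count_match` instead of masquerading as completeness.
* Read sampling is first-N, so re-auditing a file never depends on a seed;
  all randomness lives in the generator.
* CRAM is handled only when decodable without an external reference
  registry; otherwise it is a format error, not a criterion failure.

## Known limitations

* Free-text metadata detection is lexicon-exact (see above); real-archive
  recall is untested by design.
* The duplicate-sample heuristic finds suffix-pattern registrations only;
  duplicates with unrelated aliases require the declared
  previously-published list.
* BAM validation is a seven-rule subset, not a full format validator.
* Criterion decisions follow first-file/first-N sampling; heterogeneity
  deeper in a file or across later files of a study is invisible, exactly
  as in a first-file survey.
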