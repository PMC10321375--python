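# Methods

This note records the models, algorithms, parameter choices and known
limitations of `guidecraft`, in the order the pipeline applies them.

## PAM models and protospacer enumeration

A PAM model is a tuple (IUPAC pattern, side, spacer length, nominal cut
offset).  The registry ships twenty models spanning the commonly used
Cas9 variants (3'-PAM: SpCas9 NGG/NAG/NG, xCas9, SpG, SpRY, ScCas9,
FnCas9, SaCas9, SaCas9-KKH, NmeCas9, CjCas9, StCas9) and Cas12 variants
(5'-PAM: AsCas12a/LbCas12a TTTV, FnCas12a/Cas12b TTN, Cas12e TTCN,
Cas12f and CasMINI TTTR).  The set is a plain TSV
(`data/pam_models.tsv`) chosen to cover the field's standard enzymes;
only the matching semantics and the count are load-bearing — users can
point `--pam-table` at their own file.  Cut offsets are nominal
bookkeeping values (SpCas9-family blunt cut 3 nt from the PAM;
Cas12-family staggered cut ~17–18 nt distal) and do not influence
design decisions.

Enumeration scans an IUPAC-compiled regex with a zero-width lookahead so
overlapping PAMs are all found, on the forward strand and on the reverse
complement (coordinates mapped back).  Candidates are spacer intervals,
0-based half-open, in guide orientation; windows containing N are
skipped rather than expanded (expansion would inflate the candidate set
combinatorially with no informational gain).  Reports convert to
1-based inclusive coordinates at the file boundary only.

## The uniqueness database

The index counts every PAM-adjacent protospacer occurrence on both
strands of every record, keyed by the spacer sequence in guide
orientation — a spacer and its reverse complement are deliberately
distinct keys, because an sgRNA binds one strand.  Uniqueness is defined
on the spacer alone (the sgRNA does not include the PAM), and only
PAM-adjacent occurrences count: a PAM-less exact duplicate cannot be cut
but can still be found by the off-target search if it carries a relaxed
PAM.  The on-disk format is a versioned, sorted TSV with a header
(format tag, model, spacer length, genome SHA-256 digest, record and row
counts); loading verifies the tag and the row count, and design runs
verify the digest against the genome they are handed, so an index can
be built once per genome and safely reused.

## Off-target search

Sites within Hamming distance $d < D$ of the guide (default $D = 5$,
user-settable; the CLI flag counts inclusive mismatches, internally
$D = \text{flag} + 1$) are found by pigeonhole partitioning: the spacer
is split into $D$ near-equal segments; a site with fewer than $D$
mismatches must match at least one segment exactly; exact segment
occurrences come from a per-record k-mer position table (built lazily,
memoised) and each candidate window is then verified by direct base
comparison with early exit, followed by a PAM-class check.  A
brute-force window-by-window scanner lives in the test suite as an
independent oracle; the two agree field-by-field on every tested genome
and bound.

Off-target sites must carry a PAM matching a *relaxed* pattern — the
canonical pattern with its most 5'-proximal fixed position degenerated
to N (NGG → NNG, TTTV → NTTV) — because near-canonical PAMs retain
residual cleavage; the PAM penalty then down-weights them.
`canonical_pam_only=True` restricts the search to canonical PAMs.
Windows containing N are skipped.  Insertion/deletion (bulge)
off-targets are out of scope.

### CFD scoring

Each hit's score is the product of per-position mismatch penalties
(position, guide base, genome base) times a PAM penalty; a perfect match
with canonical PAM scores exactly 1.0.  The packaged penalty tables
(`cfd_mismatch_synthetic.tsv`, `pam_penalty_synthetic.tsv`) are
**synthetic stand-ins**: generated by `scripts/make_default_tables.py`
with a fixed seed, they reproduce the published tables' structure
(penalties shrink toward the PAM-proximal end, transitions milder than
transversions, mismatch penalties strictly below 1, near-canonical PAMs
strongly down-weighted) but not empirical values.  Every scoring test
asserts the algebraic contract, not specific numbers, so substituting a
published table changes scores, never correctness.  PAM penalties are
keyed by *masked* PAM strings (pattern-N positions masked back to N) to
keep the tables small across all twenty models.

Per-guide specificity is aggregated as $1/(1 + \sum_k \mathrm{CFD}_k)$
over the hit list with the on-target excluded: 1.0 with no hits,
strictly decreasing in every hit's score.  This aggregate is this
package's own convention (reported per guide alongside the raw hit
list), chosen for monotonicity and a bounded (0, 1] range.

## Guide quality flags

* **Poly-T/A**: flagged iff the spacer contains `TTTT` or `AAAA` — two
  homopolymer conditions, not a mixed A/T run.  Four consecutive T's is
  the canonical Pol III terminator; flagged guides are reported with an
  exclamation mark, never filtered.
* **Hairpin**: an exhaustive inverted-repeat scan — true iff a stem of
  ≥ `min_stem` (default 4) bases has its reverse complement downstream
  with a loop of ≥ `min_loop` (default 3) bases.  This is a sequence
  screen, not minimum-free-energy folding.  The scan covers the spacer
  plus a configurable scaffold; the default scaffold for this scan is
  empty, because the standard tracrRNA scaffold contains engineered
  hairpins that would flag every guide and make the column
  uninformative.
* **Activity**: a linear model over a 30-nt context (4-nt upstream
  flank, 20-nt spacer, 3-nt PAM, 3-nt downstream flank): intercept +
  positional single-nucleotide weights + positional dinucleotide
  weights + a piecewise GC-count term with optimum 10 G/C in the
  spacer.  The packaged weights are synthetic (same generator script,
  provenance-tagged); when the target sequence cannot supply the full
  context (near an edge, or a non-20-nt/5'-PAM model), activity is
  reported as missing (`.`), never imputed.

## Design orchestration

Candidates → uniqueness → off-target search → flags → rank.  Non-unique
guides are retained and marked `not_unique`; "prefer unique" is a rank
priority (the leading sort key when `require_unique` is set), not a
filter.  The full ranking key is (unique desc, specificity desc,
activity desc with missing last, position asc, strand), which is total
and deterministic; two runs on identical inputs are byte-identical down
to the SVG output.

**On-target exclusion in reference-free mode.**  When the caller gives
no locus, exact full-length occurrences of the target sequence in the
genome (either strand) are treated as the on-target loci and excluded
from every guide's hit list.  When the target is not a contiguous
genomic sequence (e.g. a spliced CDS), each guide falls back to
excluding its own exact canonical-PAM sites.  A consequence worth
knowing: guides spanning a splice junction have genome occurrence count
0 and are therefore reported `not_unique` — correctly, since no
contiguous genomic protospacer matches them.

**Shared guides.**  A shared guide must occur (PAM-adjacent) in every
member of the gene group; the per-gene occurrence coordinates are
attached to the report.  Uniqueness generalises to "genome count equals
the number of target genes" (each occurrence accounted for by one
target); surplus occurrences surface as off-target hits.  Requiring the
guide in *every* gene (rather than a fraction) is the implemented
policy.

## Accessories

Primer design enumerates every (start, length) pair flanking the
amplicon window under the defaults 18–25 nt, Tm 55–65 °C, GC 0.40–0.60,
pair ΔTm ≤ 3 °C, with melting temperature from the GC-fraction closed
form Tm = 64.9 + 41·(GC − 16.4)/len — deterministic and monotone in GC,
chosen over nearest-neighbor thermodynamics for testability; a 3'-tail
cross-complementarity screen (≥ 4 complementary of the last 5 nt)
rejects likely primer dimers.  Special sgRNA structures ("hairpin",
"GOLD") are opaque named insertions from a config file; the packaged
insert sequences are synthetic placeholders flagged as such in the file
header — the insertion mechanics, not the sequences, are what the
module provides.

## Synthetic data and what the tests show

`fixtures.random_genome` draws i.i.d. bases at a target GC fraction
(default scenarios use 0.45, a typical plant euchromatin value);
`plant_sites` writes protospacer cassettes at chosen positions/strands
with controlled mismatch edits and then re-randomises any background
window that accidentally falls within the cleaning distance of the
reference spacer on either strand, so the planted truth table is
*exact*, not probabilistic.  `toy_annotation` emits a deterministic
GFF3 (first gene single-exon, later genes two-exon with explicit UTRs,
CDS length divisible by 3, alternating strands) with matching truth
models.  Test genomes are 20–100 kb — large enough to exercise every
code path and the search's scaling behaviour while keeping the default
suite fast.

These genomes have no repeats, segmental duplications or biased
composition, so passing tests demonstrate algorithmic correctness
(search completeness, exact counting, deterministic ranking), not
performance or guide quality on repeat-rich real genomes, where
uniqueness rates will be far lower and hit lists far longer.

## Numerical and degenerate-input conventions

Floats are written to 6 decimals; missing values print as `.`; empty
feature sets (e.g. an absent UTR) extract to the empty string, distinct
from an error; a promoter request at a record edge truncates silently
(a gene starting at position p yields a p-nt promoter).  All
tie-breaking is lexicographic on (record, start, strand).  Errors are
typed: contract violations, registry misses, configuration gaps
(missing penalty entries name the offending triple), index format
problems, and index/genome provenance mismatches are distinct exception
classes.

## Known limitations

* Mismatch-only off-target model; no DNA/RNA bulges, no chromatin or
  experimental off-target data.
* Packaged penalty/activity tables are synthetic stand-ins (see above);
  scores are internally consistent but not publication-grade until a
  user supplies empirical tables.
* Single transcript per gene (longest, ties by ID); no trans-splicing,
  no GTF.
* Single-threaded; a 1-Mb genome with ~100 guides at the default bound
  completes in minutes, but chromosome-scale genomes will want the
  planned parallel search.
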