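# Methods

## Data model

A dataset is an ordered SNP table, an ordered sample table and exactly one
genotype payload.  Hard calls are stored as the count of `allele2`
(0 hom-allele1, 1 het, 2 hom-allele2, −1 missing), probability payloads as
`(p_AA, p_AB, p_BB)` triplets with `A = allele1`, and dosage payloads as
expected counts in `[0, 2]` of a per-SNP reference allele (slot 1 or 2,
NaN missing).  Three conventions apply everywhere:

* **Missing cells.**  Probability triplets use the all-zero triplet as the
  missing marker; a triplet summing to less than one carries implicit
  missing mass (tolerated up to `1 + 1e-6` on the high side).  Dosage
  matrices use NaN; text writers emit `NA`.  The canonical missing
  phenotype token is `-9`; writers remap it per dialect (EIGENSOFT `-99`).
* **Order preservation.**  SNP and sample order always survives
  conversion; sorting would silently break positional joins against files
  produced by other tools, so it is never implicit.
* **Allele labels are inert strings.**  They are case-preserved and never
  complemented or re-inferred as minor/major at read time.  Strand
  flipping is an explicit operation that complements labels (A↔T, C↔G) and
  leaves the payload untouched.

### Payload conversions

Hard calls expand to degenerate triplets (all mass on the observed
genotype).  Probabilities collapse to hard calls by the best-guess rule:
argmax if its probability reaches the threshold (domain `(1/3, 1]`), else
missing; exact ties are missing.  Expected dose of allele2 is
`p_AB + 2·p_BB` (allele1 symmetric), which conserves
`dose₁ + dose₂ = 2 · (mass)` for every triplet.  Dosage → hard calls is
refused unless a rounding policy is given, because it destroys
information; with the policy, doses round to the nearest genotype with
`.5` rounding toward more allele2 copies.  Dosage → probabilities is
always refused (the triplet is not identified by its mean).

### Reference-allele policy

Count/dose codings default to the minor allele as the counted allele;
`major`, `first` (allele1) and `second` are selectable.  Frequencies come
from the payload itself (observed counts for hard calls, expected counts
for probabilities, mean dose for dosages).  Tie at 0.5: minor → allele2,
major → allele1, so the two modes stay complementary.  When every
genotype is missing, minor/major resolution raises rather than guessing.

## File formats

Readers accept paths or open streams; paths ending `.gz` are compressed
transparently (the PLINK `.bed` payload stays raw binary).  Writers use a
single space, `\n` line endings, and print floats with at most six
significant digits — a fixed policy that makes closed-loop round trips
byte-stable across platforms.  Genotype tokens `A G`, `A/G` and compact
`AG` are all accepted on read; ped-family writers emit `A G` and the
MERLIN writer `A/G`.

Where a format does not declare its allele pair (ped bodies, BEAGLE
genotype rows), slots are assigned per SNP in order of first appearance —
deterministic, but a round trip through such a format can swap slots.
Swaps are harmless (the unordered genotypes are unchanged, and dataset
merging reconciles swapped pairs by slot remapping); workflows needing
slot-exact round trips pass the `snpinfo` side table, which anchors the
registry before parsing.  For the same reason the converter automatically
writes `snpinfo`/`pedinfo` side tables whenever the output dialect drops
annotation (MaCH, IMPUTE, BEAGLE, BIMBAM, PHASE/fastPHASE, HAPLOVIEW,
plain matrices): fields no single file can carry travel alongside, and
`--snpinfo`/`--pedinfo` restore them on the way back.

Dialect-specific choices worth knowing:

* **PLINK bed** is SNP-major only; individual-major mode (byte 0x00) is
  rejected loudly rather than transposed.  Pad bits are zero; the codec is
  exercised exhaustively over all 256 byte values in the tests.
* **EIGENSOFT geno** digits count allele1 copies, `9` missing.  The ind
  status column carries the group label when one is attached, otherwise
  Case/Control mapped from phenotype 2/1, otherwise `-99`.
* **MaCH** files are sample-major with `FID->IID` ids; the info file
  supplies the allele pair, and mldose doses count `Al1`.  mlprob rows
  carry `P(Al1/Al1), P(Al1/Al2)` per SNP; the homozygous-rare probability
  is the clamped complement.  Writing a dataset with no quality table
  emits `-` for Quality/Rsq rather than fabricating values.
* **IMPUTE gens** rows are `id rsid bp a1 a2` + triplets; the leading
  column holds the chromosome when known, else the SNP id.  The SNPTEST
  gen file is identical in layout; its sample file gets the two header
  rows (names, then kind codes with `0` for the id columns) and a constant
  `0` missing column — per-sample missingness bookkeeping is not tracked
  on export.
* **SHAPEIT haps / IMPUTE hap+legend** collapse haplotype pairs to
  unordered genotypes on load; phase is deliberately dropped (phased
  storage is out of scope).
* **VCF export** writes v4.2 with REF = allele1 and ALT = allele2 and no
  genome-reference check (documented caveat); GT for hard calls, DS for
  dosages (ALT dose), DS+GP for probabilities.  Import is not supported.
* **PHASE/fastPHASE** are write-only; heterozygotes list allele1 in the
  first haplotype row (phase unknown).  fastPHASE refuses multi-character
  allele labels, which its one-character-per-locus rows cannot hold.

## Quality control

All metrics are computed on the full dataset first; filters apply
afterwards.  Consequently the reported per-SNP and per-sample tables are
invariant to which thresholds are active, and sample removal uses
full-data call rates even when SNPs were removed in the same pass (SNPs
filter before samples).  Removal ledger entries cite exactly one rule —
the first violated in the fixed order call rate, MAF, HWE (then Rsq, info,
post-imputation MAF) — and all comparisons are strict (`metric < cut`).

The HWE test is the exact conditional test: given allele counts, the
heterozygote count distribution is computed by the standard two-sided
recurrence from the mode, and the p-value sums all configurations with
probability at most that observed (relative slack `1e-12` guards against
floating-point asymmetry of the up/down recurrences).  No mid-p
adjustment is applied, and HWE uses all samples, not controls only.
Probability payloads yield genotype counts only through an explicit
best-guess threshold — an expected-count fallback is never applied
silently, because it changes the null distribution of the test.

Post-imputation filtering joins a quality table (MaCH `Rsq` or IMPUTE
`info`/`certainty`) on SNP id; metrics a tool does not report are absent,
never zero-filled, and an absent metric never triggers removal.

## Merging, chunking, templates

Merging concatenates samples (primary first, `(fid, iid)` collisions are
errors) and combines SNPs by intersection (default — the strand-check
workflow requires shared SNPs) or union (absent genotypes become missing).
Allele pairs listed in swapped order are reconciled by remapping genotype
slots; `"0"` acts as a wildcard, irreconcilable pairs raise.  Dosage
merges keep the primary's reference slots and re-express secondary doses
through the allele identity.

Chunking covers `[start, end]` with windows of `chunk_len` bp advancing by
`chunk_len − overlap`; only the final chunk may be short, and coverage is
gap-free by construction (verified exhaustively in tests).  When chunk
results are merged back, a SNP present in several chunks is taken from the
chunk where its distance to the nearer chunk edge is maximal (imputation
quality degrades near boundaries); ties keep the earlier chunk.

Template bundles (IMPUTE2 chunk commands, SMARTPCA/SMARTEIGENSTRAT
parameter files with a plotting script, GenABEL phenotype + import script)
are pure functions of their inputs, emit plain 7-bit text, and are never
executed by the package.  Reference-panel paths appear as explicit
placeholder tokens; IMPUTE2 flag spelling (`-h/-l/-m`, `-int`) is used.

## Command-line interface

Flags are order-insensitive within a task; additional tasks sit in
`--new-start … --new-end` blocks, with `--merge` folding a block's data
into the dataset loaded first.  Threshold lists tolerate spaces around
`=`.  A repeated flag keeps the last value with a warning; the default
output stem is `genoconv`; `<stem>.log` is always written.

## Synthetic data

The generator draws, per SNP, a MAF uniform over `(0.05, 0.5)` by default,
a nucleotide allele pair, and genotypes i.i.d. under Hardy–Weinberg
proportions (`hwe_compliant=False` instead imposes a heterozygote deficit
with inbreeding coefficient 0.3, for exercising the HWE filter);
missingness is independent per cell at rate 0.02.  Defaults — 500 samples
× 2,000 SNPs, best-guess certainty 0.95 for generated posteriors — mirror
a small GWAS panel and are the conditions under which the validation
quantities are computed.  Every stream derives from one integer seed by
counter-based per-SNP splitting, so output is bitwise reproducible and
stable under SNP reordering.

What the generator does *not* emulate: linkage disequilibrium, population
structure, relatedness, batch effects, or genotyping-error processes.
Passing tests therefore demonstrate format and algorithmic correctness —
byte-level round trips, metric and filter semantics — not robustness to
the correlation structure of real panels.

## Validation strategy and problem sizes

Format correctness is established by closed conversion loops (A → B → C →
A must reproduce the original file after canonical token normalisation,
which only sorts the two tokens inside each unordered genotype pair) and
the QC engine by independent oracles: a brute-force log-factorial
enumeration for HWE, direct counting for MAF/call rate, and a standalone
one-pass re-implementation for filter decisions.  The shipped acceptance
script runs the loop at 500 × 2,000, the HWE comparison on 1,000 random
count triples with n ≤ 200, filtering at 200 × 400, and chunk-coverage
scans over ranges up to 10⁶ bp — sizes chosen so the whole validation
completes in well under a minute per check while keeping every code path
(missingness, swapped slots, partial bed bytes) exercised.

## Known limitations

VCF and PHASE/fastPHASE reading, PLINK 2 `.pgen`, phased storage,
family-trio logic, X-chromosome-specific HWE and stratified (case/control)
QC are out of scope.  Half-missing genotypes (one allele `0`) are treated
as fully missing.  MERLIN dat records other than `M` markers are skipped
with a warning.  The reference-allele force on hard-call/probability
payloads takes effect when a count/dose output is rendered, since those
payloads are slot-anchored and carry no standing reference designation.
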