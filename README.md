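# genoconv

Lossless conversion, quality control and management of SNP genotype data
across the file formats of GWAS and imputation tools.

## The problem

A genome-wide association study touches many tools, and each speaks its own
dialect: PLINK wants ped/map or the binary bed/bim/fam triple, EIGENSOFT a
geno/snp/ind triple, HAPLOVIEW a linkage ped plus a marker/bp table, and the
imputation tools (IMPUTE, MaCH, BEAGLE, BIMBAM, PHASE/fastPHASE) each have
their own input layout *and* their own way of reporting results — best-guess
genotypes, posterior probability triplets `(p_AA, p_AB, p_BB)`, or expected
allele doses in `[0, 2]`.  Analysts end up gluing these together with ad-hoc
scripts; genoconv replaces that glue with one library + command-line tool
built around a single in-memory representation:

* an ordered SNP table (chrom, id, cM, bp, two alleles),
* an ordered sample table (fid, iid, pat, mat, sex, phenotype),
* exactly one genotype payload — hard calls, probability triplets, or
  dosages of a per-SNP reference allele.

Every reader produces this object and every writer consumes it, so any
read-format/write-format pair composes.  Around the conversion core the
package provides the surrounding data management: QC metrics and filtering
(call rate, MAF, exact Hardy–Weinberg test; post-imputation `Rsq`/`info`
thresholds), dataset merging with allele-slot reconciliation, chromosome
chunking for parallel imputation, SNP/pedigree annotation updates, strand
flipping, numeric recodings (recodeA / expected-dose matrices) and command
templates for IMPUTE chunk runs, SMARTPCA and GenABEL.

The exact HWE test computes, conditional on the observed allele counts, the
distribution of the heterozygote count N_AB,

    P(N_AB = h) ∝ 2^h · n! / (n_AA! · h! · n_BB!) · n_A! · n_B! / (2n)!

and returns the summed probability of all configurations no more probable
than the observed one (plain exact test, no mid-p correction — PLINK's
default behaviour).

## Worked example

```sh
# synthesise a small PLINK panel
python - <<'EOF'
from genoconv.synthdata import SimSpec, gen_hardcalls
from genoconv.io_pedigree import write_ped_map
write_ped_map(gen_hardcalls(SimSpec(seed=1, n_samples=40, n_snps=12,
                                    maf_range=(0.2, 0.5))),
              "example.ped", "example.map")
EOF

# QC-filter and convert to IMPUTE input
genoconv --file example --filter-snp hwe = 1e-6,crate = 0.95,maf = 0.10 \
         --filter-indiv crate = 0.95 --oformat impute --out example_impute
cat example_impute.log
```

prints (for this seed):

```
loaded plink-ped: 12 SNPs x 40 samples
filters removed 1 SNPs and 10 samples
wrote gens: example_impute.gens (11 rows)
wrote sample: example_impute.sample (30 rows)
lossy: pedigree fields beyond ids live in the sample/pedinfo files
side tables: example_impute.snpinfo, example_impute.pedinfo
```

One SNP and ten samples fell below the call-rate cut-off (on a panel of
only 12 SNPs, the default 2% missingness means a single missing genotype
already puts a sample's call rate at 11/12 ≈ 0.92); the `.removed` ledger
lists each with its observed value.
`example_impute.gens` holds one row per retained SNP (`id rsid bp a1 a2`
followed by a probability triplet per sample — degenerate `1 0 0`-style
triplets here, since the input was hard calls), `example_impute.sample` the
two-header-row sample file SNPTEST/IMPUTE expect, and `<stem>.snpqc` / `<stem>.sampleqc` /
`<stem>.removed` the QC tables: per-SNP genotype counts, MAF, call rate and
exact-HWE p-value, per-sample call rates, and the removal ledger naming the
first violated rule for every discarded SNP or sample.  Because the gens
format cannot carry chromosome, cM or pedigree fields, the converter also
emits `.snpinfo`/`.pedinfo` side tables; feeding them back with `--snpinfo`
/ `--pedinfo` makes the reverse conversion lossless.

Multi-task commands chain conversions and merges in one call:

```sh
genoconv --file study --force pheno = aff \
         --new-start --file reference --merge --force pheno = unaff --new-end \
         --oformat plink --out merged
```

loads the study panel, merges the reference panel into it (samples
concatenated, SNP sets intersected, swapped allele pairs remapped) with
dummy case/control status marking the origin of each sample — the input
PLINK's `--flip-scan` strand check needs.

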