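"""SNP- and sample-wise quality metrics and the filtering engine.

Pre-imputation QC works on genotype counts: per-SNP minor allele frequency
(MAF), call rate and the exact test for Hardy-Weinberg equilibrium (HWE);
per-sample call rate.  Post-imputation QC filters on the quality metrics the
imputation tools report (MaCH "Rsq", IMPUTE "info") plus an allele-frequency
cut-off.  All metrics are computed on the *full* dataset first and filters
applied afterwards, so the reported metrics never depend on which thresholds
are set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import model
from .errors import QualityTableMissing, UnsupportedPayload
from .model import Dataset, HardCallMatrix, GenotypeProbabilities, DosageMatrix


@dataclass
class SnpCounts:
    """Genotype counts at one SNP; A = allele1, B = allele2."""

    n_AA: int
    n_AB: int
    n_BB: int
    n_miss: int = 0

    @property
    def n_obs(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB


def hwe_exact_p(counts: SnpCounts) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the heterozygote count
    follows a hypergeometric-type distribution; the p-value sums the
    probabilities of all heterozygote configurations no more probable than
    the observed one.  The plain exact test is used (no mid-p adjustment),
    matching PLINK's default --hardy behaviour.  Returns a value in (0, 1].
    """
    obs_hets = counts.n_AB
    obs_hom1 = counts.n_AA
    obs_hom2 = counts.n_BB
    n = obs_hets + obs_hom1 + obs_hom2
    if n < 1:
        raise ValueError("HWE test requires at least one non-missing genotype")

    rare = 2 * min(obs_hom1, obs_hom2) + obs_hets  # rare-allele copies
    if rare == 0:
        return 1.0

    probs = np.zeros(rare + 1)
    # start at the mode of the distribution, matching rare's parity
    mid = rare * (2 * n - rare) // (2 * n)
    if (rare - mid) % 2 != 0:
        mid += 1
    probs[mid] = 1.0

    hom_r = (rare - mid) // 2          # rare homozygotes at mid
    hom_c = n - mid - hom_r            # common homozygotes at mid

    het, hr, hc = mid, hom_r, hom_c
    while het > 1:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hr + 1) * (hc + 1))
        het -= 2
        hr += 1
        hc += 1

    het, hr, hc = mid, hom_r, hom_c
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * hr * hc / ((het + 2.0) * (het + 1.0))
        het += 2
        hr -= 1
        hc -= 1

    total = probs.sum()
    target = probs[obs_hets]
    # sum configurations with probability <= observed (tiny relative slack
    # guards against floating-point asymmetry of the two recurrences)
    p = probs[probs <= target * (1.0 + 1e-12)].sum() / total
    return min(1.0, float(p))


def genotype_counts(dataset: Dataset, prob_thresh: Optional[float] = None):
    """Per-SNP genotype counts as integer arrays (n_AA, n_AB, n_BB, n_miss).

    Probability payloads require ``prob_thresh``: counts are taken on the
    best-guess genotypes at that threshold (an expected-count fallback is
    deliberately *not* applied silently).
    """
    p = dataset.payload
    if isinstance(p, HardCallMatrix):
        codes = p.codes
    elif isinstance(p, GenotypeProbabilities):
        if prob_thresh is None:
            raise UnsupportedPayload(
                "genotype counts on a probability payload require a "
                "best-guess probability threshold")
        from .transform import best_guess_matrix
        codes = best_guess_matrix(p.probs, prob_thresh)
    else:
        raise UnsupportedPayload("genotype counts require hard calls or probabilities")
    n_aa = (codes == model.HOM1).sum(axis=1)
    n_ab = (codes == model.HET).sum(axis=1)
    n_bb = (codes == model.HOM2).sum(axis=1)
    n_miss = (codes == model.MISSING).sum(axis=1)
    return n_aa, n_ab, n_bb, n_miss


def snp_metrics(dataset: Dataset, prob_thresh: Optional[float] = None) -> pd.DataFrame:
    """Per-SNP table: counts, MAF, call rate and exact HWE p-value.

    MAF = min(fA, 1-fA) with fA = (2 n_AA + n_AB) / (2 n_obs); call rate =
    1 - n_miss / n_samples.  SNPs with no non-missing genotypes get NaN for
    MAF and HWE (metrics absent, not zero).

    Dosage payloads get call rate (non-missing fraction) and a MAF derived
    from the mean dose; genotype counts and HWE are not defined there.
    """
    n_samples = dataset.n_samples
    base = {
        "snp_id": [s.snp_id for s in dataset.snps],
        "chrom": [s.chrom for s in dataset.snps],
        "bp": [s.bp for s in dataset.snps],
    }
    if isinstance(dataset.payload, DosageMatrix):
        doses = dataset.payload.doses
        n_miss = np.isnan(doses).sum(axis=1)
        f1 = model.freq_allele1(dataset)
        maf = np.minimum(f1, 1.0 - f1)
        df = pd.DataFrame(base)
        df["n_AA"] = np.nan
        df["n_AB"] = np.nan
        df["n_BB"] = np.nan
        df["n_miss"] = n_miss
        df["maf"] = maf
        df["crate"] = 1.0 - n_miss / max(n_samples, 1)
        df["hwe_p"] = np.nan
        return df

    n_aa, n_ab, n_bb, n_miss = genotype_counts(dataset, prob_thresh)
    n_obs = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = (2.0 * n_aa + n_ab) / (2.0 * n_obs)
    maf = np.where(n_obs > 0, np.minimum(f1, 1.0 - f1), np.nan)
    crate = 1.0 - n_miss / max(n_samples, 1)
    hwe = np.array([
        hwe_exact_p(SnpCounts(int(a), int(h), int(b))) if o > 0 else np.nan
        for a, h, b, o in zip(n_aa, n_ab, n_bb, n_obs)
    ])
    df = pd.DataFrame(base)
    df["n_AA"] = n_aa
    df["n_AB"] = n_ab
    df["n_BB"] = n_bb
    df["n_miss"] = n_miss
    df["maf"] = maf
    df["crate"] = crate
    df["hwe_p"] = hwe
    return df


def sample_call_rates(dataset: Dataset, prob_thresh: Optional[float] = None) -> pd.DataFrame:
    """Per-sample call rate: non-missing SNPs / total SNPs."""
    p = dataset.payload
    if isinstance(p, HardCallMatrix):
        miss = p.codes == model.MISSING
    elif isinstance(p, GenotypeProbabilities):
        if prob_thresh is not None:
            from .transform import best_guess_matrix
            miss = best_guess_matrix(p.probs, prob_thresh) == model.MISSING
        else:
            miss = p.missing_mask()
    else:
        miss = np.isnan(p.doses)
    n_snps = max(dataset.n_snps, 1)
    rates = 1.0 - miss.sum(axis=0) / n_snps
    return pd.DataFrame({
        "fid": [s.fid for s in dataset.samples],
        "iid": [s.iid for s in dataset.samples],
        "crate": rates,
    })


@dataclass
class QCThresholds:
    """Filter cut-offs; every field optional (None = filter inactive).

    Comparisons are strict: an entity is removed when its metric is
    strictly below the threshold.
    """

    hwe_min: Optional[float] = None
    snp_crate_min: Optional[float] = None
    maf_min: Optional[float] = None
    sample_crate_min: Optional[float] = None
    rsq_min: Optional[float] = None
    info_min: Optional[float] = None
    prob_thresh: Optional[float] = None
    maf_thresh: Optional[float] = None

    def __post_init__(self):
        for name, lo, hi in (
            ("snp_crate_min", 0.0, 1.0), ("maf_min", 0.0, 0.5),
            ("sample_crate_min", 0.0, 1.0), ("maf_thresh", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.prob_thresh is not None and not (1.0 / 3.0 < self.prob_thresh <= 1.0):
            raise ValueError("prob_thresh must be in (1/3, 1]")

    @property
    def any_set(self) -> bool:
        return any(
            getattr(self, f) is not None
            for f in ("hwe_min", "snp_crate_min", "maf_min", "sample_crate_min",
                      "rsq_min", "info_min", "maf_thresh"))


@dataclass
class QCReport:
    """Full-dataset metrics plus the removal ledger.

    Each removed entry cites exactly one primary failed rule, the first in
    the fixed order crate, maf, hwe (then rsq, info, maf-thresh for
    post-imputation filters).
    """

    snp_metrics: pd.DataFrame
    sample_metrics: pd.DataFrame
    removed: list = field(default_factory=list)  # (entity, id, rule, observed)

    def removed_ids(self, entity: str) -> set:
        return {r[1] for r in self.removed if r[0] == entity}


def apply_filters(dataset: Dataset, thresholds: QCThresholds,
                  quality: Optional[pd.DataFrame] = None):
    """Compute all metrics on the full dataset, then filter.

    SNPs failing any active SNP-wise rule are removed first, then samples
    whose (full-data) call rate falls below the sample threshold.  Returns
    ``(filtered_dataset, QCReport)``; the report's metrics are invariant to
    which thresholds are set.
    """
    needs_quality = thresholds.rsq_min is not None or thresholds.info_min is not None
    if quality is None:
        quality = dataset.imputation_quality
    if needs_quality and quality is None:
        raise QualityTableMissing("rsq/info filtering requires an imputation quality table")

    metrics = snp_metrics(dataset, prob_thresh=thresholds.prob_thresh)
    samp = sample_call_rates(dataset, prob_thresh=thresholds.prob_thresh)

    qual_by_id = {}
    if quality is not None:
        qual_by_id = {row["snp_id"]: row for _, row in quality.iterrows()}

    removed = []
    keep_snp = np.ones(dataset.n_snps, dtype=bool)
    for i, row in metrics.iterrows():
        checks = [
            ("crate", row["crate"], thresholds.snp_crate_min),
            ("maf", row["maf"], thresholds.maf_min),
            ("hwe", row["hwe_p"], thresholds.hwe_min),
        ]
        q = qual_by_id.get(row["snp_id"])
        rsq = q.get("rsq", np.nan) if q is not None else np.nan
        info = q.get("info", np.nan) if q is not None else np.nan
        checks += [
            ("rsq", rsq, thresholds.rsq_min),
            ("info", info, thresholds.info_min),
            ("maf-thresh", row["maf"], thresholds.maf_thresh),
        ]
        for rule, value, cut in checks:
            if cut is None:
                continue
            if not np.isnan(value) and value < cut:
                removed.append(("snp", row["snp_id"], rule, float(value)))
                keep_snp[i] = False
                break

    keep_samp = np.ones(dataset.n_samples, dtype=bool)
    if thresholds.sample_crate_min is not None:
        for j, row in samp.iterrows():
            if row["crate"] < thresholds.sample_crate_min:
                removed.append(("sample", (row["fid"], row["iid"]), "crate",
                                float(row["crate"])))
                keep_samp[j] = False

    out = _take(dataset, keep_snp, keep_samp)
    return out, QCReport(snp_metrics=metrics, sample_metrics=samp, removed=removed)


def _take(dataset: Dataset, keep_snp: np.ndarray, keep_samp: np.ndarray) -> Dataset:
    """Row/column subset of a dataset by boolean masks."""
    p = dataset.payload
    if isinstance(p, HardCallMatrix):
        payload = HardCallMatrix(p.codes[np.ix_(keep_snp, keep_samp)])
    elif isinstance(p, GenotypeProbabilities):
        payload = GenotypeProbabilities(p.probs[np.ix_(keep_snp, keep_samp)])
    else:
        payload = DosageMatrix(p.doses[np.ix_(keep_snp, keep_samp)], p.ref_slot[keep_snp])
    iq = dataset.imputation_quality
    if iq is not None:
        iq = iq.loc[keep_snp].reset_index(drop=True)
    return Dataset(
        snps=[s.copy() for s, k in zip(dataset.snps, keep_snp) if k],
        samples=[s.copy() for s, k in zip(dataset.samples, keep_samp) if k],
        payload=payload,
        source_format=dataset.source_format,
        imputation_quality=iq,
    )


def write_qc_report(report: QCReport, out_stem: str) -> dict:
    """Write the per-SNP table, per-sample table and removal ledger as
    tab-separated files ``<stem>.snpqc``, ``<stem>.sampleqc``, ``<stem>.removed``."""
    paths = {
        "snpqc": f"{out_stem}.snpqc",
        "sampleqc": f"{out_stem}.sampleqc",
        "removed": f"{out_stem}.removed",
    }
    report.snp_metrics.to_csv(paths["snpqc"], sep="\t", index=False, na_rep="NA")
    report.sample_metrics.to_csv(paths["sampleqc"], sep="\t", index=False, na_rep="NA")
    with open(paths["removed"], "w") as fh:
        fh.write("entity\tid\trule\tobserved\n")
        for entity, ident, rule, obs in report.removed:
            name = ident if isinstance(ident, str) else " ".join(ident)
            fh.write(f"{entity}\t{name}\t{rule}\t{obs:.6g}\n")
    return paths
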