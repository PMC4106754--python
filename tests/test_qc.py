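import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from genoconv.errors import QualityTableMissing, UnsupportedPayload
from genoconv.model import Dataset, HardCallMatrix, SampleRecord, SnpRecord
from genoconv.qc import (
    QCThresholds,
    SnpCounts,
    apply_filters,
    hwe_exact_p,
    sample_call_rates,
    snp_metrics,
)
from genoconv.synthdata import SimSpec, gen_hardcalls


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Independent brute-force exact HWE p-value.

    Enumerates every heterozygote count with the observed allele margins and
    sums the conditional probabilities (direct log-factorial formula) of all
    configurations no more probable than the observed one.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def log_prob(h):
        haa = (n_a - h) // 2
        hbb = (n_b - h) // 2
        return (h * np.log(2)
                + gammaln(n + 1) - gammaln(haa + 1) - gammaln(h + 1) - gammaln(hbb + 1)
                + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))

    hets = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
    probs = np.exp([log_prob(h) for h in hets])
    probs /= probs.sum()
    obs = probs[hets.index(n_ab)]
    return min(1.0, probs[probs <= obs * (1 + 1e-12)].sum())


class TestHweExact:
    def test_monomorphic_snp_has_p_one(self):
        assert hwe_exact_p(SnpCounts(50, 0, 0)) == 1.0

    @pytest.mark.parametrize("counts", [(25, 50, 25), (0, 100, 0), (3, 4, 3),
                                        (1, 0, 1), (10, 1, 10)])
    def test_matches_enumeration_oracle_on_known_counts(self, counts):
        assert hwe_exact_p(SnpCounts(*counts)) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12)

    def test_matches_enumeration_oracle_on_random_counts(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            p = hwe_exact_p(SnpCounts(n_aa, n_ab, n_bb))
            worst = max(worst, abs(p - hwe_enumeration_oracle(n_aa, n_ab, n_bb)))
            assert 0.0 < p <= 1.0
        assert worst <= 1e-12

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(SnpCounts(0, 0, 0))


def _dataset_from_codes(codes):
    codes = np.asarray(codes, dtype=np.int8)
    snps = [SnpRecord("1", f"rs{i+1}", 0.0, 100 * (i + 1), "A", "G")
            for i in range(codes.shape[0])]
    samples = [SampleRecord(f"F{j+1}", f"I{j+1}") for j in range(codes.shape[1])]
    return Dataset(snps, samples, HardCallMatrix(codes))


class TestMetrics:
    def test_maf_and_call_rate_from_counts(self):
        ds = _dataset_from_codes([[0] * 3 + [1] * 4 + [2] * 3])
        m = snp_metrics(ds)
        assert m.loc[0, "maf"] == pytest.approx(0.5)   # fA = 10/20
        assert m.loc[0, "crate"] == 1.0

    def test_monomorphic_maf_zero(self):
        ds = _dataset_from_codes([[0] * 10])
        assert snp_metrics(ds).loc[0, "maf"] == 0.0

    def test_missing_lowers_call_rate(self):
        ds = _dataset_from_codes([[0] * 8 + [-1] * 2])
        assert snp_metrics(ds).loc[0, "crate"] == pytest.approx(0.8)

    def test_all_missing_snp_metrics_absent(self):
        ds = _dataset_from_codes([[-1, -1], [0, 1]])
        m = snp_metrics(ds)
        assert np.isnan(m.loc[0, "maf"]) and np.isnan(m.loc[0, "hwe_p"])

    def test_probability_payload_requires_threshold(self, small_prob_dataset):
        with pytest.raises(UnsupportedPayload):
            snp_metrics(small_prob_dataset)
        m = snp_metrics(small_prob_dataset, prob_thresh=0.8)
        assert len(m) == small_prob_dataset.n_snps

    def test_sample_call_rates(self):
        ds = _dataset_from_codes([[0, -1], [1, -1], [2, -1], [0, 0]])
        rates = sample_call_rates(ds)
        assert rates["crate"].tolist() == [1.0, 0.25]


class TestApplyFilters:
    def test_no_thresholds_is_identity(self, small_dataset):
        out, rep = apply_filters(small_dataset, QCThresholds())
        assert out.n_snps == small_dataset.n_snps
        assert out.n_samples == small_dataset.n_samples
        assert rep.removed == []

    def test_maf_filter_cites_maf_rule(self):
        # maf 0.05 (one het in 10 samples), full call rate
        ds = _dataset_from_codes([[0] * 9 + [1], [0] * 5 + [1] * 5])
        thr = QCThresholds(hwe_min=1e-6, snp_crate_min=0.95, maf_min=0.10)
        out, rep = apply_filters(ds, thr)
        assert rep.removed == [("snp", "rs1", "maf", pytest.approx(0.05))]
        assert [s.snp_id for s in out.snps] == ["rs2"]

    def test_first_failed_rule_order_is_crate_maf_hwe(self):
        # SNP fails both crate and maf -> cited rule must be crate
        ds = _dataset_from_codes([[0] * 5 + [-1] * 5])
        thr = QCThresholds(snp_crate_min=0.95, maf_min=0.10)
        _, rep = apply_filters(ds, thr)
        assert rep.removed[0][2] == "crate"

    def test_rsq_filter_needs_and_uses_quality_table(self):
        ds = _dataset_from_codes([[0, 1, 2], [0, 0, 1]])
        thr = QCThresholds(rsq_min=0.3)
        with pytest.raises(QualityTableMissing):
            apply_filters(ds, thr)
        quality = pd.DataFrame({"snp_id": ["rs1", "rs2"], "rsq": [0.25, 0.9]})
        out, rep = apply_filters(ds, thr, quality=quality)
        assert rep.removed == [("snp", "rs1", "rsq", 0.25)]
        assert [s.snp_id for s in out.snps] == ["rs2"]

    def test_metrics_invariant_to_thresholds(self, small_dataset):
        _, rep_none = apply_filters(small_dataset, QCThresholds())
        _, rep_all = apply_filters(small_dataset, QCThresholds(
            hwe_min=1e-6, snp_crate_min=0.95, maf_min=0.10, sample_crate_min=0.95))
        pd.testing.assert_frame_equal(rep_none.snp_metrics, rep_all.snp_metrics)
        pd.testing.assert_frame_equal(rep_none.sample_metrics, rep_all.sample_metrics)

    def test_maf_threshold_monotonicity(self):
        ds = gen_hardcalls(SimSpec(seed=5, n_samples=60, n_snps=40, missing_rate=0.02))
        kept = []
        for maf_min in (0.05, 0.15, 0.25, 0.35):
            out, _ = apply_filters(ds, QCThresholds(maf_min=maf_min))
            kept.append({s.snp_id for s in out.snps})
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_retained_plus_removed_equals_input(self, small_dataset):
        thr = QCThresholds(hwe_min=1e-3, snp_crate_min=0.97, maf_min=0.15,
                           sample_crate_min=0.97)
        out, rep = apply_filters(small_dataset, thr)
        assert out.n_snps + len(rep.removed_ids("snp")) == small_dataset.n_snps
        assert out.n_samples + len(rep.removed_ids("sample")) == small_dataset.n_samples

    def test_sample_filter_uses_full_data_call_rate(self):
        # sample 3 misses half the SNPs; removal must cite its full-data rate
        codes = np.zeros((4, 3), dtype=np.int8)
        codes[:2, 2] = -1
        ds = _dataset_from_codes(codes)
        out, rep = apply_filters(ds, QCThresholds(sample_crate_min=0.9))
        assert rep.removed == [("sample", ("F3", "I3"), "crate", 0.5)]
        assert out.n_samples == 2
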