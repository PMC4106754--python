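import numpy as np
import pytest

from genoconv.errors import BadMagic, InconsistentColumnCount, LengthMismatch
from genoconv.io_pedigree import read_ped_map
from genoconv.io_plink_binary import read_bed
from genoconv.manage import merge
from genoconv.model import MISSING, validate
from genoconv.qc import SnpCounts, genotype_counts, hwe_exact_p
from genoconv.synthdata import (
    SimSpec,
    gen_broken_fixture,
    gen_hardcalls,
    gen_probs,
)


class TestGenHardcalls:
    def test_same_seed_is_bitwise_identical(self):
        spec = SimSpec(seed=42, n_samples=30, n_snps=20)
        a, b = gen_hardcalls(spec), gen_hardcalls(spec)
        assert np.array_equal(a.payload.codes, b.payload.codes)
        assert [s.allele1 for s in a.snps] == [s.allele1 for s in b.snps]
        assert validate(a).ok

    def test_zero_missing_rate_means_no_missing_cells(self):
        ds = gen_hardcalls(SimSpec(seed=1, n_samples=50, n_snps=50, missing_rate=0.0))
        assert (ds.payload.codes != MISSING).all()

    def test_allele_frequency_tracks_target_maf(self):
        # binomial bound: |f_obs - maf| < 4*sqrt(p(1-p)/2n) for >= 95% of SNPs
        spec = SimSpec(seed=9, n_samples=500, n_snps=300, missing_rate=0.0)
        ds = gen_hardcalls(spec)
        ok = 0
        for i in range(spec.n_snps):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,)))
            maf = rng.uniform(*spec.maf_range)
            f_obs = ds.payload.codes[i].sum() / (2 * spec.n_samples)
            bound = 4 * np.sqrt(maf * (1 - maf) / (2 * spec.n_samples))
            ok += abs(f_obs - maf) < bound
        assert ok / spec.n_snps >= 0.95

    def test_hwe_compliant_data_shows_no_disequilibrium(self):
        ds = gen_hardcalls(SimSpec(seed=3, n_samples=200, n_snps=1000,
                                   missing_rate=0.0))
        n_aa, n_ab, n_bb, _ = genotype_counts(ds)
        ps = [hwe_exact_p(SnpCounts(int(a), int(h), int(b)))
              for a, h, b in zip(n_aa, n_ab, n_bb)]
        assert np.median(ps) >= 0.3

    def test_non_compliant_data_shows_het_deficit(self):
        ds = gen_hardcalls(SimSpec(seed=3, n_samples=300, n_snps=200,
                                   missing_rate=0.0, hwe_compliant=False))
        n_aa, n_ab, n_bb, _ = genotype_counts(ds)
        ps = [hwe_exact_p(SnpCounts(int(a), int(h), int(b)))
              for a, h, b in zip(n_aa, n_ab, n_bb)]
        assert np.median(ps) < 1e-3


class TestGenProbs:
    def test_certainty_one_gives_degenerate_triplets(self, small_dataset):
        probs = gen_probs(small_dataset, 1.0)
        mass = probs.payload.probs.max(axis=2)
        observed = small_dataset.payload.codes != MISSING
        assert (mass[observed] == 1.0).all()

    def test_triplets_sum_to_one(self, small_dataset):
        probs = gen_probs(small_dataset, 0.8)
        sums = probs.payload.probs.sum(axis=2)
        observed = small_dataset.payload.codes != MISSING
        assert np.allclose(sums[observed], 1.0, atol=1e-12)
        assert (sums[~observed] == 0.0).all()


class TestBrokenFixtures:
    def test_bad_magic_fixture_triggers_bad_magic(self, tmp_path):
        p = gen_broken_fixture("bad-magic", 1, str(tmp_path))
        with pytest.raises(BadMagic):
            read_bed(p["bed"], p["bim"], p["fam"])

    def test_truncated_bed_triggers_length_mismatch(self, tmp_path):
        p = gen_broken_fixture("truncated-bed", 1, str(tmp_path))
        with pytest.raises(LengthMismatch):
            read_bed(p["bed"], p["bim"], p["fam"])

    def test_ragged_ped_triggers_column_error(self, tmp_path):
        p = gen_broken_fixture("ragged-ped", 1, str(tmp_path))
        with pytest.raises(InconsistentColumnCount):
            read_ped_map(p["ped"], p["map"])

    def test_swapped_alleles_pair_merges_cleanly(self, tmp_path):
        p = gen_broken_fixture("swapped-alleles", 1, str(tmp_path))
        a = read_ped_map(p["primary_ped"], p["primary_map"])
        b = read_ped_map(p["secondary_ped"], p["secondary_map"])
        m = merge(a, b)
        assert m.n_samples == a.n_samples + b.n_samples

    def test_id_collision_fixture_fails_validation(self, tmp_path):
        p = gen_broken_fixture("id-collision", 1, str(tmp_path))
        ds = read_ped_map(p["ped"], p["map"])
        rep = validate(ds)
        assert any(rule == "duplicate sample id" for _, _, rule in rep.violations)
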