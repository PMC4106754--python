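import io

import numpy as np
import pytest

from genoconv.errors import (
    AlleleMismatch,
    DuplicateSample,
    EmptyResult,
    IdCollision,
    JoinKeyAmbiguity,
    PayloadMismatch,
    SampleListMismatch,
)
from genoconv.manage import (
    ChunkSpec,
    ForceDirective,
    attach_group_labels,
    force_assign,
    hybrid_ids,
    make_chunks,
    merge,
    merge_chunk_results,
    read_pedinfo,
    read_snpinfo,
    subset,
    update_info,
    write_lists,
)
from genoconv.model import SampleRecord, SnpRecord, convert_payload
from genoconv.synthdata import SimSpec, gen_hardcalls


def _rename_samples(ds, prefix):
    out = ds.copy()
    for j, s in enumerate(out.samples):
        s.fid, s.iid = f"{prefix}F{j}", f"{prefix}I{j}"
    return out


def _genotype_freqs(ds, snp_id):
    """Unordered-genotype frequency table for one SNP (slot independent)."""
    i = ds.snp_index()[snp_id]
    snp = ds.snps[i]
    out = {}
    for c in ds.payload.codes[i]:
        if c == -1:
            key = "missing"
        else:
            key = tuple(sorted([snp.allele1] * (2 - c) + [snp.allele2] * c))
        out[key] = out.get(key, 0) + 1
    return out


class TestMerge:
    def test_samples_concatenate_primary_first(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        m = merge(a, b)
        assert m.n_samples == a.n_samples + b.n_samples
        assert m.samples[0].fid.startswith("a")
        assert np.array_equal(m.payload.codes[:, :a.n_samples], a.payload.codes)

    def test_duplicate_sample_rejected(self, small_dataset):
        with pytest.raises(DuplicateSample):
            merge(small_dataset, small_dataset.copy())

    def test_union_fills_missing(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        b = subset(b, remove_snps=[b.snps[0].snp_id])
        m = merge(a, b, snp_policy="union")
        assert m.n_snps == a.n_snps
        i = m.snp_index()[a.snps[0].snp_id]
        assert (m.payload.codes[i, a.n_samples:] == -1).all()

    def test_intersect_drops_private_snps(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        b = subset(b, remove_snps=[b.snps[0].snp_id])
        m = merge(a, b)
        assert m.n_snps == a.n_snps - 1

    def test_swapped_allele_pair_is_remapped(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        for s in b.snps:
            s.allele1, s.allele2 = s.allele2, s.allele1
        b.payload.codes[b.payload.codes >= 0] = 2 - b.payload.codes[b.payload.codes >= 0]
        m = merge(a, b)
        sid = a.snps[0].snp_id
        fa = _genotype_freqs(a, sid)
        fb = _genotype_freqs(b, sid)
        fm = _genotype_freqs(m, sid)
        assert fm == {k: fa.get(k, 0) + fb.get(k, 0) for k in set(fa) | set(fb)}

    def test_irreconcilable_alleles_rejected(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        b.snps[0].allele1, b.snps[0].allele2 = "Z", "Q"
        with pytest.raises(AlleleMismatch):
            merge(a, b)

    def test_payload_kinds_must_match(self, small_dataset, small_prob_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_prob_dataset, "b")
        with pytest.raises(PayloadMismatch):
            merge(a, b)

    def test_merge_then_subset_retracts_to_primary(self, small_dataset):
        a = _rename_samples(small_dataset, "a")
        b = _rename_samples(small_dataset, "b")
        m = merge(a, b)
        back = subset(m, keep_samples=[s.key for s in a.samples],
                      keep_snps=[s.snp_id for s in a.snps])
        assert np.array_equal(back.payload.codes, a.payload.codes)
        assert [s.key for s in back.samples] == [s.key for s in a.samples]


class TestSubset:
    def test_keep_preserves_order(self, small_dataset):
        ids = [s.snp_id for s in small_dataset.snps]
        out = subset(small_dataset, keep_snps=[ids[4], ids[1]])
        assert [s.snp_id for s in out.snps] == [ids[1], ids[4]]

    def test_unknown_id_warns_not_fails(self, small_dataset):
        with pytest.warns(UserWarning, match="unknown ids"):
            out = subset(small_dataset, keep_snps=[small_dataset.snps[0].snp_id, "rsX"])
        assert out.n_snps == 1

    def test_empty_result_is_error(self, small_dataset):
        with pytest.raises(EmptyResult):
            subset(small_dataset, keep_snps=["rsX"])


class TestChunks:
    def test_documented_example(self):
        bounds = make_chunks(ChunkSpec("1", 1, 10_000_000, 5_000_000, 500_000))
        assert bounds == [(1, 5_000_000), (4_500_001, 9_500_000),
                          (9_000_001, 10_000_000)]

    def test_short_range_single_chunk(self):
        assert make_chunks(ChunkSpec("1", 10, 500, 5_000, 100)) == [(10, 500)]

    def test_every_bp_covered_small_ranges(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            start = int(rng.integers(1, 1000))
            end = start + int(rng.integers(10, 100_000))
            length = int(rng.integers(50, 5000))
            overlap = int(rng.integers(1, length))
            bounds = make_chunks(ChunkSpec("1", start, end, length, overlap))
            covered = np.zeros(end - start + 1, dtype=bool)
            for lo, hi in bounds:
                covered[max(lo, start) - start:hi - start + 1] = True
            assert covered.all()
            for (lo1, hi1), (lo2, _) in zip(bounds, bounds[1:]):
                assert lo2 <= hi1  # consecutive chunks overlap

    def test_merge_chunk_results_edge_distance_rule(self):
        snps1 = [SnpRecord("1", "rsA", 0, 4_700_000, "A", "G")]
        snps2 = [SnpRecord("1", "rsA", 0, 4_700_000, "A", "G")]
        samples = [SampleRecord("F1", "I1")]
        from genoconv.model import Dataset, HardCallMatrix
        c1 = Dataset(snps1, samples, HardCallMatrix(np.array([[1]], dtype=np.int8)))
        c2 = Dataset([s.copy() for s in snps2], [s.copy() for s in samples],
                     HardCallMatrix(np.array([[2]], dtype=np.int8)))
        out = merge_chunk_results([c1, c2], [(1, 5_000_000), (4_500_001, 9_500_000)])
        # edge distance 300,000 in chunk 1 vs 199,999 in chunk 2
        assert out.payload.codes[0, 0] == 1

    def test_merge_chunk_results_conserves_distinct_snps(self, small_dataset):
        half = small_dataset.n_snps // 2
        ids = [s.snp_id for s in small_dataset.snps]
        c1 = subset(small_dataset, keep_snps=ids[:half + 3])
        c2 = subset(small_dataset, keep_snps=ids[half - 3:])
        hi1 = c1.snps[-1].bp + 1
        lo2 = c2.snps[0].bp - 1
        out = merge_chunk_results([c1, c2], [(1, hi1), (lo2, small_dataset.snps[-1].bp)])
        assert out.n_snps == len(set(ids))
        assert [s.snp_id for s in out.snps] == ids

    def test_sample_mismatch_rejected(self, small_dataset):
        c2 = _rename_samples(small_dataset, "x")
        with pytest.raises(SampleListMismatch):
            merge_chunk_results([small_dataset, c2], [(1, 10), (5, 20)])


class TestUpdateInfo:
    def test_snpinfo_fills_positions(self, small_dataset):
        stripped = small_dataset.copy()
        for s in stripped.snps:
            s.bp, s.chrom = 0, "0"
        info = [s.copy() for s in small_dataset.snps]
        out = update_info(stripped, snpinfo=info)
        assert [s.bp for s in out.snps] == [s.bp for s in small_dataset.snps]

    def test_empty_pheno_field_keeps_existing(self, tiny_dataset):
        rec = SampleRecord("F1", "I1", phenotype="")
        out = update_info(tiny_dataset, pedinfo=[rec])
        assert out.samples[0].phenotype == "2"

    def test_pedinfo_for_absent_sample_warns(self, tiny_dataset):
        rec = SampleRecord("FX", "IX", phenotype="1")
        with pytest.warns(UserWarning, match="absent samples"):
            update_info(tiny_dataset, pedinfo=[rec])

    def test_duplicate_join_key_rejected(self, tiny_dataset):
        recs = [SampleRecord("F1", "I1"), SampleRecord("F1", "I1")]
        with pytest.raises(JoinKeyAmbiguity):
            update_info(tiny_dataset, pedinfo=recs)


class TestListsRoundTrip:
    def test_snplist_and_pedlist_shapes(self, tiny_dataset):
        sink = io.StringIO()
        write_lists(tiny_dataset, "snplist", sink)
        assert sink.getvalue().splitlines() == ["rs1", "rs2"]
        sink = io.StringIO()
        write_lists(tiny_dataset, "pedlist", sink)
        assert all(len(l.split()) == 2 for l in sink.getvalue().splitlines())

    def test_snpinfo_roundtrip_restores_annotation(self, small_dataset, tmp_path):
        write_lists(small_dataset, "snpinfo", tmp_path / "x.snpinfo")
        stripped = small_dataset.copy()
        for s in stripped.snps:
            s.bp, s.chrom, s.cm = 0, "0", 0.0
        out = update_info(stripped, snpinfo=read_snpinfo(tmp_path / "x.snpinfo"))
        assert [(s.chrom, s.bp) for s in out.snps] == \
               [(s.chrom, s.bp) for s in small_dataset.snps]

    def test_pedinfo_roundtrip(self, small_dataset, tmp_path):
        write_lists(small_dataset, "pedinfo", tmp_path / "x.pedinfo")
        recs = read_pedinfo(tmp_path / "x.pedinfo")
        assert [(r.fid, r.iid, r.sex, r.phenotype) for r in recs] == \
               [(s.fid, s.iid, s.sex, s.phenotype) for s in small_dataset.samples]


class TestIdsForcesLabels:
    def test_hybrid_id_pattern(self):
        samples = [SampleRecord("FAM1", "IND1"), SampleRecord("FAM2", "IND2")]
        assert hybrid_ids(samples, ["fid", "iid"]) == ["FAM1_IND1", "FAM2_IND2"]
        assert hybrid_ids(samples, ["fid", "iid"], ".") == ["FAM1.IND1", "FAM2.IND2"]

    def test_duplicate_hybrid_id_rejected(self):
        samples = [SampleRecord("F1", "X"), SampleRecord("F2", "X")]
        with pytest.raises(IdCollision):
            hybrid_ids(samples, ["iid"])

    def test_force_pheno_coding(self, tiny_dataset):
        aff = force_assign(tiny_dataset, ForceDirective("pheno", "aff"))
        assert {s.phenotype for s in aff.samples} == {"2"}
        unaff = force_assign(tiny_dataset, ForceDirective("pheno", "unaff"))
        assert {s.phenotype for s in unaff.samples} == {"1"}

    def test_force_ref_allele_reexpresses_doses(self, small_dataset):
        dose = convert_payload(small_dataset, "dosage")
        forced = force_assign(dose, ForceDirective("ref-allele", "major"))
        flipped = forced.payload.ref_slot != dose.payload.ref_slot
        assert flipped.any()
        i = int(np.nonzero(flipped)[0][0])
        mask = ~np.isnan(dose.payload.doses[i])
        assert np.allclose(forced.payload.doses[i][mask],
                           2.0 - dose.payload.doses[i][mask])

    def test_group_labels_default_and_last_wins(self, tiny_dataset):
        with pytest.warns(UserWarning):
            labels = attach_group_labels(
                tiny_dataset.samples,
                [("I1", "CEU"), ("I1", "YRI"), ("ZZZ", "MEX")])
        assert labels == {"I1": "YRI", "I2": "Unknown", "I3": "Unknown"}
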