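import pandas as pd

from genoconv.io_imputation import CovariateTable
from genoconv.manage import ChunkSpec, make_chunks
from genoconv.templates import eigensoft_bundle, genabel_bundle, impute_commands


class TestImputeCommands:
    def test_one_command_per_chunk_with_bounds(self):
        chunks = make_chunks(ChunkSpec("1", 1, 10_000_000, 5_000_000, 500_000))
        bundle = impute_commands(chunks, "study")
        cmds = bundle.files["study_impute_commands.txt"].splitlines()
        assert len(cmds) == len(chunks)
        for (lo, hi), cmd in zip(chunks, cmds):
            assert f"-int {lo} {hi}" in cmd

    def test_limits_table_row_count(self):
        chunks = [(1, 100), (51, 200)]
        bundle = impute_commands(chunks, "study")
        rows = bundle.files["study_chunk_limits.txt"].splitlines()
        assert len(rows) == 1 + len(chunks)  # header + one row per chunk

    def test_placeholders_present_in_every_command(self):
        bundle = impute_commands([(1, 100)], "study")
        for cmd in bundle.files["study_impute_commands.txt"].splitlines():
            for token in bundle.placeholders:
                assert token in cmd

    def test_identical_inputs_give_identical_bundles(self):
        a = impute_commands([(1, 100), (51, 200)], "s")
        b = impute_commands([(1, 100), (51, 200)], "s")
        assert a.files == b.files


class TestEigensoftBundle:
    def test_four_files_referencing_rendered_triplet(self):
        bundle = eigensoft_bundle("study")
        assert len(bundle.files) == 4
        par = bundle.files["study_smartpca.par"]
        assert "genotypename: study.geno" in par
        assert "snpname: study.snp" in par
        assert "indivname: study.ind" in par

    def test_stem_prefixes_every_filename(self):
        bundle = eigensoft_bundle("study")
        assert all(name.startswith("study") for name in bundle.files)


class TestGenabelBundle:
    def test_pheno_rows_match_samples(self, tiny_dataset):
        bundle = genabel_bundle("study", tiny_dataset.samples)
        lines = bundle.files["study.pheno"].splitlines()
        assert len(lines) == 1 + tiny_dataset.n_samples
        assert lines[0] == "id\tsex\tpheno"

    def test_script_references_ped_map_and_pheno(self, tiny_dataset):
        bundle = genabel_bundle("study", tiny_dataset.samples)
        script = bundle.files["study_genabel_import.R"]
        for name in ("study.ped", "study.map", "study.pheno"):
            assert name in script

    def test_covariates_add_columns(self, tiny_dataset):
        covars = CovariateTable(
            pd.DataFrame({"fid": ["F1"], "iid": ["I1"], "age": ["40"]}),
            kinds={"age": "C"})
        bundle = genabel_bundle("study", tiny_dataset.samples, covars)
        header = bundle.files["study.pheno"].splitlines()[0].split("\t")
        assert header == ["id", "sex", "pheno", "age"]
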