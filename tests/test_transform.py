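import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoconv.errors import (
    MonomorphicAmbiguity,
    NonNucleotideAllele,
    UnknownSnpId,
    UnsupportedPayload,
)
from genoconv.model import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    ConversionPolicy,
    SnpRecord,
    convert_payload,
)
from genoconv.synthdata import gen_probs
from genoconv.transform import (
    ReferenceAllelePolicy,
    best_guess,
    expected_dose,
    flip_strand,
    render_recodeA,
    resolve_reference,
)

_snp = SnpRecord("1", "rs1", 0.0, 100, "A", "G")


class TestExpectedDose:
    @pytest.mark.parametrize("triplet,ref,expect", [
        ((1.0, 0.0, 0.0), 2, 0.0),
        ((0.25, 0.5, 0.25), 2, 1.0),
        ((0.25, 0.5, 0.25), 1, 1.0),
        ((0.1, 0.2, 0.7), 2, 1.6),
    ])
    def test_known_values(self, triplet, ref, expect):
        assert expected_dose(triplet, ref) == pytest.approx(expect)

    def test_zero_triplet_is_missing(self):
        assert math.isnan(expected_dose((0.0, 0.0, 0.0), 2))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)))
    def test_dose_conservation_across_reference_choice(self, t):
        # dose(allele1) + dose(allele2) = 2 * total mass, for any triplet
        if sum(t) == 0:
            return
        total = expected_dose(t, 1) + expected_dose(t, 2)
        assert total == pytest.approx(2 * sum(t))


class TestBestGuess:
    @pytest.mark.parametrize("triplet,thresh,expect", [
        ((0.95, 0.03, 0.02), 0.9, HOM1),
        ((0.5, 0.3, 0.2), 0.9, MISSING),
        ((0.5, 0.5, 0.0), 0.5, MISSING),   # exact tie
        ((0.1, 0.2, 0.7), 0.6, HOM2),
    ])
    def test_known_calls(self, triplet, thresh, expect):
        assert best_guess(triplet, thresh) == expect

    def test_threshold_domain_enforced(self):
        with pytest.raises(ValueError):
            best_guess((1, 0, 0), 0.2)

    def test_inverts_degenerate_triplets(self, small_dataset):
        probs = convert_payload(small_dataset, "probabilities")
        back = convert_payload(probs, "hardcalls",
                               ConversionPolicy(prob_thresh=1 / 3 + 1e-9))
        assert np.array_equal(back.payload.codes, small_dataset.payload.codes)


class TestResolveReference:
    def test_minor_allele_from_counts(self):
        assert resolve_reference(_snp, (9, 0, 1), ReferenceAllelePolicy("minor")) == 2

    def test_tie_rules(self):
        assert resolve_reference(_snp, (5, 0, 5), ReferenceAllelePolicy("minor")) == 2
        assert resolve_reference(_snp, (5, 0, 5), ReferenceAllelePolicy("major")) == 1

    def test_first_ignores_counts(self):
        assert resolve_reference(_snp, (0, 0, 0), ReferenceAllelePolicy("first")) == 1

    def test_all_missing_frequencies_ambiguous(self):
        with pytest.raises(MonomorphicAmbiguity):
            resolve_reference(_snp, (0, 0, 0), ReferenceAllelePolicy("minor"))


class TestFlipStrand:
    def test_complement_and_involution(self, tiny_dataset):
        flipped = flip_strand(tiny_dataset, ["rs1"])
        assert (flipped.snps[0].allele1, flipped.snps[0].allele2) == ("T", "C")
        assert np.array_equal(flipped.payload.codes, tiny_dataset.payload.codes)
        twice = flip_strand(flipped, ["rs1"])
        assert (twice.snps[0].allele1, twice.snps[0].allele2) == ("A", "G")

    def test_unknown_snp_and_non_nucleotide(self, tiny_dataset):
        with pytest.raises(UnknownSnpId):
            flip_strand(tiny_dataset, ["rsX"])
        ds = tiny_dataset.copy()
        ds.snps[0].allele1 = "0"
        with pytest.raises(NonNucleotideAllele):
            flip_strand(ds, ["rs1"])


class TestRecodeA:
    def test_counts_mode_cells_are_integer_or_na(self, small_dataset):
        sink = io.StringIO()
        render_recodeA(small_dataset, ReferenceAllelePolicy("minor"), "counts",
                       add_dominance=False, sink=sink)
        lines = sink.getvalue().splitlines()
        header = lines[0].split()
        assert header[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        assert all("_" in c for c in header[6:])
        for line in lines[1:]:
            assert set(line.split()[6:]) <= {"0", "1", "2", "NA"}

    def test_recodeAD_adds_het_indicator(self, tiny_dataset):
        sink = io.StringIO()
        render_recodeA(tiny_dataset, ReferenceAllelePolicy("second"), "counts",
                       add_dominance=True, sink=sink)
        lines = sink.getvalue().splitlines()
        assert "rs1_HET" in lines[0].split()
        # sample I2 is het at rs1: additive 1, dominance 1
        row = dict(zip(lines[0].split(), lines[2].split()))
        assert row["rs1_G"] == "1" and row["rs1_HET"] == "1"
        # sample I1 is hom: dominance 0
        row1 = dict(zip(lines[0].split(), lines[1].split()))
        assert row1["rs1_HET"] == "0"

    def test_expected_mode_requires_non_hardcall_payload(self, small_dataset):
        with pytest.raises(UnsupportedPayload):
            render_recodeA(small_dataset, ReferenceAllelePolicy("minor"), "expected",
                           add_dominance=False, sink=io.StringIO())
        probs = gen_probs(small_dataset, 0.9)
        sink = io.StringIO()
        render_recodeA(probs, ReferenceAllelePolicy("minor"), "expected",
                       add_dominance=False, sink=sink)
        cells = [c for line in sink.getvalue().splitlines()[1:]
                 for c in line.split()[6:] if c != "NA"]
        assert all(0.0 <= float(c) <= 2.0 for c in cells)
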