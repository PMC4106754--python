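import numpy as np
import pytest

from genoconv import model
from genoconv.errors import UnsupportedConversion
from genoconv.model import (
    ConversionPolicy,
    Dataset,
    DosageMatrix,
    GenotypeProbabilities,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
    convert_payload,
    validate,
)


class TestValidate:
    def test_well_formed_dataset_yields_empty_report(self, tiny_dataset):
        assert validate(tiny_dataset).ok

    def test_probability_sum_above_one_is_flagged(self, tiny_dataset):
        probs = np.zeros((2, 3, 3))
        probs[0, 0] = (0.5, 0.6, 0.2)  # sums to 1.3
        ds = Dataset(tiny_dataset.snps, tiny_dataset.samples,
                     GenotypeProbabilities(probs))
        rep = validate(ds)
        assert any("sum > 1" in rule for _, _, rule in rep.violations)

    def test_duplicate_sample_id_is_flagged(self, tiny_dataset):
        ds = tiny_dataset.copy()
        ds.samples[1].fid, ds.samples[1].iid = "F1", "I1"
        rep = validate(ds)
        assert ("sample", 1, "duplicate sample id") in rep.violations

    def test_shape_mismatch_and_bad_dose_are_flagged(self, tiny_dataset):
        doses = np.array([[2.5, 0.0, 1.0], [0.0, 1.0, 2.0]])
        ds = Dataset(tiny_dataset.snps, tiny_dataset.samples,
                     DosageMatrix(doses, np.array([1, 2], dtype=np.int8)))
        rep = validate(ds)
        assert any("outside [0, 2]" in rule for _, _, rule in rep.violations)


class TestConvertPayload:
    def test_hardcalls_to_degenerate_probabilities(self, tiny_dataset):
        out = convert_payload(tiny_dataset, "probabilities")
        probs = out.payload.probs
        assert tuple(probs[0, 2]) == (0.0, 0.0, 1.0)   # hom allele2
        assert tuple(probs[0, 1]) == (0.0, 1.0, 0.0)   # het
        assert tuple(probs[1, 1]) == (0.0, 0.0, 0.0)   # missing -> zero mass

    def test_probabilities_to_expected_dose_of_allele2(self, tiny_dataset):
        probs = np.zeros((2, 3, 3))
        probs[:, :] = (0.25, 0.5, 0.25)
        ds = Dataset(tiny_dataset.snps, tiny_dataset.samples,
                     GenotypeProbabilities(probs))
        out = convert_payload(ds, "dosage", ConversionPolicy(ref_policy="second"))
        assert np.allclose(out.payload.doses, 1.0)  # 0.5 + 2 * 0.25

    def test_probabilities_to_hardcalls_requires_threshold(self, tiny_dataset):
        ds = convert_payload(tiny_dataset, "probabilities")
        with pytest.raises(UnsupportedConversion):
            convert_payload(ds, "hardcalls")

    def test_dosage_to_hardcalls_requires_rounding_policy(self, tiny_dataset):
        ds = convert_payload(tiny_dataset, "dosage")
        with pytest.raises(UnsupportedConversion):
            convert_payload(ds, "hardcalls")
        back = convert_payload(ds, "hardcalls", ConversionPolicy(round_doses=True))
        assert np.array_equal(back.payload.codes, tiny_dataset.payload.codes)

    def test_hard_prob_hard_loop_is_identity(self, small_dataset):
        probs = convert_payload(small_dataset, "probabilities")
        back = convert_payload(probs, "hardcalls", ConversionPolicy(prob_thresh=0.5))
        assert np.array_equal(back.payload.codes, small_dataset.payload.codes)


def test_freq_allele1_counts_observed_alleles():
    snps = [SnpRecord("1", "rs1", 0.0, 1, "A", "G")]
    samples = [SampleRecord(f"F{i}", f"I{i}") for i in range(5)]
    codes = np.array([[0, 0, 1, 2, -1]], dtype=np.int8)  # 4 observed: fA = 5/8
    ds = Dataset(snps, samples, HardCallMatrix(codes))
    assert model.freq_allele1(ds)[0] == pytest.approx(5 / 8)
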