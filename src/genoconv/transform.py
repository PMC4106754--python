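"""Payload transforms: expected dosage, best-guess genotypes, reference-allele
resolution, recodeA/recodeAD rendering and strand flipping.

These are the arithmetic primitives behind numeric genotype codings used in
regression-based association analysis: counts of a reference allele (0/1/2)
for hard calls, and expected allele doses in [0, 2] for imputed genotype
probability distributions.  The default reference allele is the minor
allele; callers can force the first, the second or the major allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import model
from .errors import (
    MonomorphicAmbiguity,
    NonNucleotideAllele,
    UnknownSnpId,
    UnsupportedPayload,
)
from .model import MISSING, Dataset, HardCallMatrix, GenotypeProbabilities, DosageMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

NA_TOKEN = "NA"


@dataclass
class ReferenceAllelePolicy:
    """Which allele a numeric coding counts: minor (default), major, first
    (allele1 verbatim) or second (allele2 verbatim)."""

    mode: str = "minor"

    def __post_init__(self):
        if self.mode not in ("minor", "major", "first", "second"):
            raise ValueError(f"unknown reference-allele mode {self.mode!r}")


def expected_dose(triplet, ref_slot: int) -> float:
    """Expected count of the reference allele given (pAA, pAB, pBB).

    ``ref_slot`` 2 counts allele2 (dose = pAB + 2*pBB); slot 1 counts
    allele1.  An all-zero triplet means a missing cell and yields NaN.
    """
    paa, pab, pbb = triplet
    if paa == 0.0 and pab == 0.0 and pbb == 0.0:
        return float("nan")
    if ref_slot == 2:
        return pab + 2.0 * pbb
    return pab + 2.0 * paa


def best_guess(triplet, prob_thresh: float):
    """Maximum-a-posteriori genotype, or MISSING below threshold or on ties.

    ``prob_thresh`` must exceed 1/3 (otherwise the argmax is not unique in
    the worst case); ties between the top genotypes always yield MISSING.
    """
    if not (1.0 / 3.0 < prob_thresh <= 1.0):
        raise ValueError("prob_thresh must be in (1/3, 1]")
    t = tuple(triplet)
    best = max(t)
    if best < prob_thresh:
        return MISSING
    idx = [i for i, v in enumerate(t) if v == best]
    if len(idx) > 1:
        return MISSING
    return idx[0]


def best_guess_matrix(probs: np.ndarray, prob_thresh: float) -> np.ndarray:
    """Vectorised :func:`best_guess` over a (n_snps, n_samples, 3) array."""
    if not (1.0 / 3.0 < prob_thresh <= 1.0):
        raise ValueError("prob_thresh must be in (1/3, 1]")
    best = probs.max(axis=2)
    codes = probs.argmax(axis=2).astype(np.int8)
    ties = (probs == best[:, :, None]).sum(axis=2) > 1
    codes[(best < prob_thresh) | ties] = MISSING
    return codes


def resolve_reference(snp, counts, policy: ReferenceAllelePolicy) -> int:
    """Return the reference slot (1 or 2) for one SNP.

    ``counts`` is (n_AA, n_AB, n_BB); needed only for minor/major modes.
    Tie rules: equal frequencies -> allele2 for minor, allele1 for major.
    """
    if policy.mode == "first":
        return 1
    if policy.mode == "second":
        return 2
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise MonomorphicAmbiguity(
            f"cannot resolve {policy.mode} allele of {snp.snp_id}: all genotypes missing")
    f1 = (2 * n_aa + n_ab) / (2.0 * n)
    if policy.mode == "minor":
        return 1 if f1 < 0.5 else 2
    return 1 if f1 >= 0.5 else 2


def flip_strand(dataset: Dataset, snp_ids) -> Dataset:
    """Complement the allele labels of the listed SNPs (A<->T, C<->G).

    The genotype payload is untouched: allele slots keep their meaning, only
    the labels change, which is exactly what harmonising two datasets typed
    on opposite strands requires.  Flipping twice is the identity.
    """
    ds = dataset.copy()
    index = ds.snp_index()
    for sid in snp_ids:
        if sid not in index:
            raise UnknownSnpId(sid)
        snp = ds.snps[index[sid]]
        for attr in ("allele1", "allele2"):
            a = getattr(snp, attr)
            if a not in _COMPLEMENT:
                raise NonNucleotideAllele(f"{sid}: allele {a!r} is not A/C/G/T")
        snp.allele1 = _COMPLEMENT[snp.allele1]
        snp.allele2 = _COMPLEMENT[snp.allele2]
    return ds


def _counted_doses(dataset: Dataset, policy: ReferenceAllelePolicy, dose_mode: str):
    """Per-SNP reference slots plus the (n_snps, n_samples) dose matrix."""
    p = dataset.payload
    if dose_mode == "counts":
        if not isinstance(p, HardCallMatrix):
            raise UnsupportedPayload("counts mode requires a hard-call payload")
    elif dose_mode == "expected":
        if isinstance(p, HardCallMatrix):
            raise UnsupportedPayload(
                "expected mode requires probabilities or dosage payload")
    else:
        raise ValueError(f"unknown dose_mode {dose_mode!r}")

    converted = model.convert_payload(
        dataset, "dosage", model.ConversionPolicy(ref_policy=policy.mode))
    dm = converted.payload
    return dm.ref_slot, dm.doses


def _fmt_dose(v: float, integral: bool) -> str:
    if np.isnan(v):
        return NA_TOKEN
    if integral:
        return str(int(round(v)))
    from ._io_util import fmt_float
    return fmt_float(v)


def render_recodeA(dataset: Dataset, policy: ReferenceAllelePolicy,
                   dose_mode: str, add_dominance: bool, sink) -> "dict":
    """Write a PLINK raw (recodeA / recodeAD) table.

    Header: FID IID PAT MAT SEX PHENOTYPE then one column per SNP named
    ``<snp_id>_<counted allele>``; recodeAD appends ``<snp_id>_HET``
    dominance-indicator columns.  Cells are 0/1/2/NA in counts mode and
    reals in [0, 2] (or NA) in expected mode.
    """
    from ._io_util import open_sink

    slots, doses = _counted_doses(dataset, policy, dose_mode)
    integral = dose_mode == "counts"
    p = dataset.payload
    het = p.codes == model.HET if isinstance(p, HardCallMatrix) else None

    with open_sink(sink) as fh:
        head = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        for snp, slot in zip(dataset.snps, slots):
            allele = snp.allele1 if slot == 1 else snp.allele2
            head.append(f"{snp.snp_id}_{allele}")
            if add_dominance:
                head.append(f"{snp.snp_id}_HET")
        fh.write(" ".join(head) + "\n")
        for j, s in enumerate(dataset.samples):
            row = [s.fid, s.iid, s.pat, s.mat, str(s.sex), s.phenotype]
            for i in range(dataset.n_snps):
                row.append(_fmt_dose(doses[i, j], integral))
                if add_dominance:
                    if het is not None:
                        code = p.codes[i, j]
                        row.append(NA_TOKEN if code == MISSING else str(int(code == model.HET)))
                    else:
                        row.append(NA_TOKEN)
            fh.write(" ".join(row) + "\n")
    return {"rows": dataset.n_samples, "columns": len(head)}
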