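"""Canonical in-memory representation of SNP genotype datasets.

Every reader in the I/O modules produces a :class:`Dataset` and every writer
consumes one.  A dataset couples an ordered SNP table, an ordered sample
table and exactly one genotype payload, which is one of

* hard calls   -- per (SNP, sample) an unordered allele pair, coded as the
  count of ``allele2`` (0 = hom-allele1, 1 = het, 2 = hom-allele2,
  -1 = missing);
* genotype probabilities -- per (SNP, sample) a triplet
  ``(pAA, pAB, pBB)`` with ``A = allele1`` and ``B = allele2``;
* dosages      -- per (SNP, sample) the expected count in [0, 2] of a
  per-SNP reference allele (slot 1 or 2), NaN = missing.

SNP and sample order is always preserved; sorting is an explicit management
operation, never an implicit side effect of conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import UnsupportedConversion

#: genotype codes used by HardCallMatrix (count of allele2)
MISSING = -1
HOM1 = 0
HET = 1
HOM2 = 2

#: tolerance above which a probability triplet sum counts as invalid
PROB_SUM_TOL = 1e-6

MISSING_PHENO = "-9"  # canonical internal missing-phenotype token


@dataclass
class SnpRecord:
    """Annotation for one biallelic marker.

    ``chrom`` uses PLINK labels ("1".."22", "X", "Y", "MT", "0" unknown),
    ``cm`` is genetic distance in centimorgan (0 = unknown), ``bp`` the
    1-based base-pair position (0 = unknown) and ``allele1``/``allele2``
    the two allele labels ("0" = unknown).  Labels are case-preserved and
    never complemented implicitly.
    """

    chrom: str
    snp_id: str
    cm: float
    bp: int
    allele1: str
    allele2: str

    def copy(self) -> "SnpRecord":
        return replace(self)


@dataclass
class SampleRecord:
    """Pedigree fields for one individual (PLINK fam conventions)."""

    fid: str
    iid: str
    pat: str = "0"
    mat: str = "0"
    sex: int = 0
    phenotype: str = MISSING_PHENO

    def copy(self) -> "SampleRecord":
        return replace(self)

    @property
    def key(self) -> tuple:
        return (self.fid, self.iid)


class HardCallMatrix:
    """Hard-call payload: int8 codes, shape (n_snps, n_samples)."""

    kind = "hardcalls"

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2:
            raise ValueError("hard-call codes must be 2-D (n_snps, n_samples)")
        self.codes = codes

    @property
    def shape(self):
        return self.codes.shape

    def copy(self) -> "HardCallMatrix":
        return HardCallMatrix(self.codes.copy())

    def __eq__(self, other):
        return isinstance(other, HardCallMatrix) and np.array_equal(self.codes, other.codes)


class GenotypeProbabilities:
    """Probability payload: float64, shape (n_snps, n_samples, 3).

    The all-zero triplet is the missing-cell convention; a triplet sum
    below one is interpreted as implicit missing mass.
    """

    kind = "probabilities"

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 3 or probs.shape[2] != 3:
            raise ValueError("probabilities must have shape (n_snps, n_samples, 3)")
        self.probs = probs

    @property
    def shape(self):
        return self.probs.shape[:2]

    def missing_mask(self) -> np.ndarray:
        return self.probs.sum(axis=2) == 0.0

    def copy(self) -> "GenotypeProbabilities":
        return GenotypeProbabilities(self.probs.copy())

    def __eq__(self, other):
        return isinstance(other, GenotypeProbabilities) and np.array_equal(self.probs, other.probs)


class DosageMatrix:
    """Dosage payload: expected allele count in [0, 2], NaN = missing.

    ``ref_slot[i]`` says which allele of SNP *i* the dose counts:
    1 for ``allele1``, 2 for ``allele2``.
    """

    kind = "dosage"

    def __init__(self, doses: np.ndarray, ref_slot: np.ndarray):
        doses = np.asarray(doses, dtype=np.float64)
        if doses.ndim != 2:
            raise ValueError("doses must be 2-D (n_snps, n_samples)")
        ref_slot = np.asarray(ref_slot, dtype=np.int8)
        if ref_slot.shape != (doses.shape[0],):
            raise ValueError("ref_slot must have one entry per SNP")
        self.doses = doses
        self.ref_slot = ref_slot

    @property
    def shape(self):
        return self.doses.shape

    def copy(self) -> "DosageMatrix":
        return DosageMatrix(self.doses.copy(), self.ref_slot.copy())

    def __eq__(self, other):
        return (
            isinstance(other, DosageMatrix)
            and np.array_equal(self.doses, other.doses, equal_nan=True)
            and np.array_equal(self.ref_slot, other.ref_slot)
        )


Payload = Union[HardCallMatrix, GenotypeProbabilities, DosageMatrix]


@dataclass
class Dataset:
    """One genotype dataset: SNPs x samples plus exactly one payload."""

    snps: list
    samples: list
    payload: Payload
    source_format: str = ""
    imputation_quality: Optional[pd.DataFrame] = None

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "Dataset":
        return Dataset(
            snps=[s.copy() for s in self.snps],
            samples=[s.copy() for s in self.samples],
            payload=self.payload.copy(),
            source_format=self.source_format,
            imputation_quality=(
                None if self.imputation_quality is None else self.imputation_quality.copy()
            ),
        )

    def snp_index(self) -> dict:
        return {s.snp_id: i for i, s in enumerate(self.snps)}

    def sample_index(self) -> dict:
        return {s.key: i for i, s in enumerate(self.samples)}


@dataclass
class ValidationReport:
    """List of invariant violations, each (entity, index, rule)."""

    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, entity: str, index, rule: str) -> None:
        self.violations.append((entity, index, rule))


def validate(dataset: Dataset) -> ValidationReport:
    """Check every dataset invariant; returns a report, never raises.

    Empty report iff the dataset is well-formed.
    """
    rep = ValidationReport()
    n_snps, n_samples = dataset.n_snps, dataset.n_samples

    if dataset.payload.shape != (n_snps, n_samples):
        rep.add("dataset", None,
                f"payload shape {dataset.payload.shape} != ({n_snps}, {n_samples})")

    for i, snp in enumerate(dataset.snps):
        if snp.bp < 0:
            rep.add("snp", i, "bp < 0")
        if snp.cm < 0:
            rep.add("snp", i, "cm < 0")
        if snp.allele1 == snp.allele2 and snp.allele1 != "0":
            rep.add("snp", i, "allele1 == allele2")

    seen = {}
    for j, sample in enumerate(dataset.samples):
        if sample.key in seen:
            rep.add("sample", j, "duplicate sample id")
        seen[sample.key] = j
        if sample.sex not in (0, 1, 2):
            rep.add("sample", j, f"sex {sample.sex} not in {{0,1,2}}")

    p = dataset.payload
    if isinstance(p, HardCallMatrix):
        bad = ~np.isin(p.codes, (MISSING, HOM1, HET, HOM2))
        for i, j in zip(*np.nonzero(bad)):
            rep.add("genotype", (int(i), int(j)), f"invalid code {p.codes[i, j]}")
    elif isinstance(p, GenotypeProbabilities):
        neg = (p.probs < 0).any(axis=2)
        over = p.probs.sum(axis=2) > 1.0 + PROB_SUM_TOL
        for i, j in zip(*np.nonzero(neg)):
            rep.add("genotype", (int(i), int(j)), "negative probability")
        for i, j in zip(*np.nonzero(over)):
            rep.add("genotype", (int(i), int(j)), "triplet sum > 1+tol")
    elif isinstance(p, DosageMatrix):
        with np.errstate(invalid="ignore"):
            bad = (p.doses < 0) | (p.doses > 2)
        bad &= ~np.isnan(p.doses)
        for i, j in zip(*np.nonzero(bad)):
            rep.add("genotype", (int(i), int(j)), f"dose {p.doses[i, j]} outside [0, 2]")
        for i in np.nonzero(~np.isin(p.ref_slot, (1, 2)))[0]:
            rep.add("snp", int(i), f"ref_slot {p.ref_slot[i]} not in {{1,2}}")

    if dataset.imputation_quality is not None and len(dataset.imputation_quality) != n_snps:
        rep.add("dataset", None, "imputation_quality row count != n_snps")

    return rep


@dataclass
class ConversionPolicy:
    """Options steering payload conversion.

    prob_thresh   -- posterior threshold for probabilities -> hard calls
                     (argmax kept only if its probability >= threshold).
    ref_policy    -- reference-allele policy for conversions producing a
                     dosage payload ("minor", "major", "first", "second").
    round_doses   -- allow dosage -> hard calls by rounding to the nearest
                     genotype (required; without it the conversion errors).
    """

    prob_thresh: Optional[float] = None
    ref_policy: str = "minor"
    round_doses: bool = False


def freq_allele1(dataset: Dataset) -> np.ndarray:
    """Per-SNP frequency of allele1, NaN where no information.

    Works on any payload: observed allele counts for hard calls, expected
    counts for probabilities, and the dose mean for dosage payloads.
    """
    p = dataset.payload
    with np.errstate(invalid="ignore"):
        if isinstance(p, HardCallMatrix):
            c = p.codes
            n_obs = (c >= 0).sum(axis=1)
            count2 = np.where(c >= 0, c, 0).sum(axis=1)
            return np.where(n_obs > 0, 1.0 - count2 / (2.0 * np.maximum(n_obs, 1)), np.nan)
        if isinstance(p, GenotypeProbabilities):
            mass = p.probs.sum(axis=2)
            n_obs = (mass > 0).sum(axis=1)
            exp1 = (2 * p.probs[:, :, 0] + p.probs[:, :, 1]).sum(axis=1)
            tot = 2.0 * mass.sum(axis=1)
            return np.where(n_obs > 0, exp1 / np.where(tot > 0, tot, 1.0), np.nan)
        mean_dose = np.nanmean(np.where(np.isnan(p.doses), np.nan, p.doses), axis=1)
        f_ref = mean_dose / 2.0
        return np.where(p.ref_slot == 1, f_ref, 1.0 - f_ref)


def _resolve_ref_slots(dataset: Dataset, mode: str) -> np.ndarray:
    """Per-SNP reference slot (1/2) under a reference-allele policy."""
    n = dataset.n_snps
    if mode == "first":
        return np.ones(n, dtype=np.int8)
    if mode == "second":
        return np.full(n, 2, dtype=np.int8)
    f1 = freq_allele1(dataset)
    f1 = np.where(np.isnan(f1), 0.5, f1)  # no data: fall back to tie rule
    if mode == "minor":
        # tie -> allele2
        return np.where(f1 < 0.5, 1, 2).astype(np.int8)
    if mode == "major":
        # tie -> allele1
        return np.where(f1 >= 0.5, 1, 2).astype(np.int8)
    raise ValueError(f"unknown reference-allele mode {mode!r}")


def convert_payload(dataset: Dataset, target_kind: str,
                    policy: Optional[ConversionPolicy] = None) -> Dataset:
    """Return a new dataset whose payload has ``target_kind``.

    Supported kinds: ``hardcalls``, ``probabilities``, ``dosage``.
    Hard calls become degenerate probability triplets (all mass on the
    observed genotype, all-zero for missing).  Probabilities become hard
    calls through the best-guess rule (requires ``policy.prob_thresh``) and
    dosages through the expected-dose formula.  Dosage -> hard calls
    requires ``policy.round_doses``.
    """
    policy = policy or ConversionPolicy()
    p = dataset.payload
    if p.kind == target_kind:
        return dataset.copy()

    out = dataset.copy()
    if isinstance(p, HardCallMatrix):
        if target_kind == "probabilities":
            probs = np.zeros((dataset.n_snps, dataset.n_samples, 3))
            for g in (HOM1, HET, HOM2):
                probs[:, :, g][p.codes == g] = 1.0
            out.payload = GenotypeProbabilities(probs)
        elif target_kind == "dosage":
            slots = _resolve_ref_slots(dataset, policy.ref_policy)
            count2 = p.codes.astype(np.float64)
            count2[p.codes == MISSING] = np.nan
            doses = np.where(slots[:, None] == 2, count2, 2.0 - count2)
            out.payload = DosageMatrix(doses, slots)
        else:
            raise UnsupportedConversion(f"hardcalls -> {target_kind}")
    elif isinstance(p, GenotypeProbabilities):
        if target_kind == "hardcalls":
            if policy.prob_thresh is None:
                raise UnsupportedConversion(
                    "probabilities -> hardcalls requires a probability threshold")
            from .transform import best_guess_matrix
            out.payload = HardCallMatrix(best_guess_matrix(p.probs, policy.prob_thresh))
        elif target_kind == "dosage":
            slots = _resolve_ref_slots(dataset, policy.ref_policy)
            d2 = p.probs[:, :, 1] + 2.0 * p.probs[:, :, 2]
            d1 = p.probs[:, :, 1] + 2.0 * p.probs[:, :, 0]
            doses = np.where(slots[:, None] == 2, d2, d1)
            doses = np.where(p.missing_mask(), np.nan, doses)
            out.payload = DosageMatrix(doses, slots)
        else:
            raise UnsupportedConversion(f"probabilities -> {target_kind}")
    else:  # DosageMatrix
        if target_kind == "hardcalls":
            if not policy.round_doses:
                raise UnsupportedConversion(
                    "dosage -> hardcalls requires an explicit rounding policy")
            count2 = np.where(p.ref_slot[:, None] == 2, p.doses, 2.0 - p.doses)
            codes = np.floor(count2 + 0.5)  # .5 rounds toward more allele2
            codes = np.clip(codes, 0, 2)
            codes[np.isnan(count2)] = MISSING
            out.payload = HardCallMatrix(codes.astype(np.int8))
        else:
            raise UnsupportedConversion(f"dosage -> {target_kind}")
    return out
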