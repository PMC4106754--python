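"""Deterministic synthetic genotype datasets and broken fixtures.

The generator draws biallelic SNPs with per-SNP minor allele frequencies
uniform over a range, genotypes under Hardy-Weinberg equilibrium (or with a
fixed inbreeding excess when ``hwe_compliant`` is off), independent
missingness, and nucleotide allele pairs.  Every stream derives from one
integer seed through per-SNP counter-based splitting, so output is bitwise
reproducible and stable under SNP reordering.

Fixture files for reader tests are written through the package's own
writers and then (for the broken variants) deliberately corrupted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .model import (
    MISSING,
    Dataset,
    GenotypeProbabilities,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("C", "G")]


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset.

    Defaults mimic a small GWAS panel: 500 individuals, 2,000 common SNPs
    (MAF 0.05-0.5), 2% missing genotypes, HWE-compliant, and imputation
    posteriors that put 95% mass on the true genotype.
    """

    seed: int
    n_samples: int = 500
    n_snps: int = 2000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    hwe_compliant: bool = True
    certainty: float = 0.95

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (1.0 / 3.0 < self.certainty <= 1.0):
            raise ValueError("certainty must lie in (1/3, 1]")


def _snp_rng(seed: int, i: int) -> np.random.Generator:
    # counter-based split: one independent stream per SNP index
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))


def gen_hardcalls(spec: SimSpec) -> Dataset:
    """Draw a hard-call dataset under the spec's study conditions.

    allele2 is the designated minor allele (frequency = the drawn MAF);
    genotype probabilities follow HWE when ``hwe_compliant``, otherwise a
    heterozygote deficit with inbreeding coefficient 0.3 is imposed.
    """
    meta_rng = _snp_rng(spec.seed, spec.n_snps)  # stream for sample table
    samples = [
        SampleRecord(f"F{j+1}", f"I{j+1}", "0", "0",
                     int(meta_rng.integers(1, 3)),
                     str(int(meta_rng.integers(1, 3))))
        for j in range(spec.n_samples)
    ]
    snps, codes = [], np.empty((spec.n_snps, spec.n_samples), dtype=np.int8)
    lo, hi = spec.maf_range
    for i in range(spec.n_snps):
        rng = _snp_rng(spec.seed, i)
        maf = rng.uniform(lo, hi)
        a1, a2 = _ALLELE_PAIRS[rng.integers(0, len(_ALLELE_PAIRS))]
        snps.append(SnpRecord("1", f"rs{i+1}", 0.0, 1000 * (i + 1), a1, a2))
        f = maf  # frequency of allele2
        if spec.hwe_compliant:
            p = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
        else:
            F = 0.3  # inbreeding excess -> systematic het deficit
            p = np.array([
                (1 - f) ** 2 + F * f * (1 - f),
                2 * f * (1 - f) * (1 - F),
                f ** 2 + F * f * (1 - f),
            ])
        codes[i] = rng.choice(3, size=spec.n_samples, p=p)
        if spec.missing_rate > 0:
            codes[i, rng.random(spec.n_samples) < spec.missing_rate] = MISSING
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="synthetic")


def gen_probs(dataset: Dataset, certainty: float, seed: int = 0) -> Dataset:
    """Replace a hard-call payload with sharp probability triplets.

    The true genotype receives probability ``certainty``; the remaining
    mass is split evenly between the other two genotypes, so a best-guess
    call at any threshold below ``certainty`` recovers the original hard
    calls exactly.  Missing cells become all-zero triplets.
    """
    if not isinstance(dataset.payload, HardCallMatrix):
        raise ValueError("gen_probs needs a hard-call dataset")
    if not (1.0 / 3.0 < certainty <= 1.0):
        raise ValueError("certainty must lie in (1/3, 1]")
    codes = dataset.payload.codes
    n_snps, n_samples = codes.shape
    rest = (1.0 - certainty) / 2.0
    probs = np.full((n_snps, n_samples, 3), rest)
    for g in range(3):
        probs[:, :, g][codes == g] = certainty
    probs[codes == MISSING] = 0.0
    out = dataset.copy()
    out.payload = GenotypeProbabilities(probs)
    return out


BROKEN_KINDS = ("bad-magic", "truncated-bed", "ragged-ped",
                "swapped-alleles", "id-collision")


def gen_broken_fixture(kind: str, seed: int, out_dir: str) -> dict:
    """Write a small file set that triggers exactly one reader error.

    Returns role -> path.  Kinds: bad-magic / truncated-bed (corrupt PLINK
    bed triples), ragged-ped (inconsistent ped columns), swapped-alleles
    (a merge pair whose second member lists the allele pair in reverse
    order -- exercises slot remapping, not an error), id-collision (two
    identical (fid, iid) pairs).
    """
    from .io_pedigree import write_ped_map
    from .io_plink_binary import write_bed

    os.makedirs(out_dir, exist_ok=True)
    spec = SimSpec(seed=seed, n_samples=6, n_snps=4, missing_rate=0.0)
    ds = gen_hardcalls(spec)
    paths = {}
    if kind in ("bad-magic", "truncated-bed"):
        bed = os.path.join(out_dir, f"{kind}.bed")
        bim = os.path.join(out_dir, f"{kind}.bim")
        fam = os.path.join(out_dir, f"{kind}.fam")
        write_bed(ds, bed, bim, fam)
        data = open(bed, "rb").read()
        with open(bed, "wb") as fh:
            fh.write(b"\x00\x00" + data[2:] if kind == "bad-magic" else data[:-1])
        paths = {"bed": bed, "bim": bim, "fam": fam}
    elif kind == "ragged-ped":
        ped = os.path.join(out_dir, "ragged.ped")
        map_ = os.path.join(out_dir, "ragged.map")
        write_ped_map(ds, ped, map_)
        lines = open(ped).read().splitlines()
        lines[1] = " ".join(lines[1].split()[:-1])  # drop one allele token
        with open(ped, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        paths = {"ped": ped, "map": map_}
    elif kind == "swapped-alleles":
        primary = ds
        secondary = gen_hardcalls(SimSpec(seed=seed + 1, n_samples=4, n_snps=4,
                                          missing_rate=0.0))
        for s_p, s_s in zip(primary.snps, secondary.snps):
            s_s.snp_id = s_p.snp_id
            s_s.allele1, s_s.allele2 = s_p.allele2, s_p.allele1
            s_s.bp = s_p.bp
        for j, s in enumerate(secondary.samples):
            s.fid, s.iid = f"G{j+1}", f"J{j+1}"
        secondary.payload.codes[:] = 2 - secondary.payload.codes
        p1 = (os.path.join(out_dir, "primary.ped"), os.path.join(out_dir, "primary.map"))
        p2 = (os.path.join(out_dir, "secondary.ped"), os.path.join(out_dir, "secondary.map"))
        write_ped_map(primary, *p1)
        write_ped_map(secondary, *p2)
        paths = {"primary_ped": p1[0], "primary_map": p1[1],
                 "secondary_ped": p2[0], "secondary_map": p2[1]}
    elif kind == "id-collision":
        ds.samples[1].fid = ds.samples[0].fid
        ds.samples[1].iid = ds.samples[0].iid
        ped = os.path.join(out_dir, "collide.ped")
        map_ = os.path.join(out_dir, "collide.map")
        write_ped_map(ds, ped, map_)
        paths = {"ped": ped, "map": map_}
    else:
        raise ValueError(f"unknown defect kind {kind!r}; choose from {BROKEN_KINDS}")
    return paths
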