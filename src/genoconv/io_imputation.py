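"""Readers and writers for genotype-probability and dosage formats used
around imputation.

Covered: IMPUTE gens/sample and hap/legend reference files, SHAPEIT
haps/sample, MaCH mldose/mlprob/mlgeno plus info, BEAGLE gprobs, PLINK
dosage, SNPTEST gen + sample (with covariates) and VCF export.  IMPUTE,
BEAGLE and SHAPEIT files are SNP-major (one row per SNP); MaCH files are
sample-major with "FID->IID" id tokens.

Floats are printed with at most six significant digits, a fixed policy that
makes closed-loop round trips byte-stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import model
from ._io_util import WriteReport, fmt_float, open_sink, open_source, sink_name
from .errors import (
    BadIdToken,
    HeaderMismatch,
    InconsistentColumnCount,
    KindUndeclared,
    MalformedLine,
    MissingAlleleLabels,
    MissingPosition,
    OrientationMismatch,
    SampleMismatch,
    TripletCountMismatch,
    UnsupportedPayload,
)
from .model import (
    MISSING,
    Dataset,
    DosageMatrix,
    GenotypeProbabilities,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)

_CHROM_LABELS = {str(c) for c in range(0, 27)} | {"X", "Y", "XY", "MT", "M"}


# ---------------------------------------------------------------------------
# covariates (SNPTEST sample files)

@dataclass
class CovariateTable:
    """Per-sample covariates with declared SNPTEST kind codes.

    Kinds: D discrete, C continuous, B binary, P phenotype.  One row per
    (fid, iid); every exported column must have a declared kind.
    """

    data: pd.DataFrame                     # columns: fid, iid, <covariates...>
    kinds: dict = field(default_factory=dict)

    @property
    def names(self) -> list:
        return [c for c in self.data.columns if c not in ("fid", "iid")]

    def validate_kinds(self) -> None:
        for name in self.names:
            kind = self.kinds.get(name)
            if kind not in ("D", "C", "B", "P"):
                raise KindUndeclared(f"covariate {name!r} has no declared kind")


def read_covar(source, covar_names: Optional[list] = None,
               covar_types: Optional[list] = None) -> CovariateTable:
    """PLINK covariate file: header FID IID then covariate columns."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise HeaderMismatch("empty covariate file")
    header = rows[0]
    if [h.upper() for h in header[:2]] != ["FID", "IID"]:
        raise HeaderMismatch("covariate header must start FID IID")
    names = header[2:]
    recs = []
    for ln, tok in enumerate(rows[1:], 2):
        if len(tok) != len(header):
            raise InconsistentColumnCount(ln, "ragged covariate file")
        recs.append(tok)
    df = pd.DataFrame(recs, columns=["fid", "iid"] + names)
    if covar_names:
        keep = [n for n in names if n in set(covar_names)]
        df = df[["fid", "iid"] + keep]
        names = keep
    kinds = {}
    if covar_types:
        for name, kind in zip(names, covar_types):
            kinds[name] = kind
    return CovariateTable(df, kinds)


def write_snptest_sample(samples: list, covars: Optional[CovariateTable],
                         sink) -> WriteReport:
    """SNPTEST sample file: two header rows (names, then kind codes with 0
    for the id/missing columns), one data row per sample in genotype-file
    order."""
    names, kinds, by_key = [], [], {}
    if covars is not None and covars.names:
        covars.validate_kinds()
        names = covars.names
        kinds = [covars.kinds[n] for n in names]
        sample_keys = {(s.fid, s.iid) for s in samples}
        for _, row in covars.data.iterrows():
            key = (row["fid"], row["iid"])
            if key not in sample_keys:
                raise SampleMismatch(
                    f"covariate row for unknown sample {key[0]} {key[1]}")
            by_key[key] = [row[n] for n in names]
    with open_sink(sink) as fh:
        fh.write(" ".join(["ID_1", "ID_2", "missing"] + names) + "\n")
        fh.write(" ".join(["0", "0", "0"] + kinds) + "\n")
        for s in samples:
            vals = by_key.get((s.fid, s.iid), ["NA"] * len(names))
            fh.write(" ".join([s.fid, s.iid, "0"] + [str(v) for v in vals]) + "\n")
    return WriteReport(files={"sample": sink_name(sink)},
                       rows={"sample": len(samples)})


def read_sample(source) -> list:
    """IMPUTE/SHAPEIT/SNPTEST sample file -> SampleRecord list."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) < 2 or rows[0][:2] != ["ID_1", "ID_2"]:
        raise HeaderMismatch("sample file must start with ID_1 ID_2 header rows")
    samples = []
    for tok in rows[2:]:
        samples.append(SampleRecord(tok[0], tok[1]))
    return samples


# ---------------------------------------------------------------------------
# IMPUTE gens (and the identical SNPTEST gen layout)

def _looks_like_chrom(token: str) -> bool:
    return token in _CHROM_LABELS or (token.startswith("chr") and token[3:] in _CHROM_LABELS)


def read_gens(gens, sample=None, pedinfo: Optional[list] = None,
              snpinfo: Optional[list] = None) -> Dataset:
    """IMPUTE gens: one row per SNP -- "id rsid bp a1 a2" then a probability
    triplet per sample.  A leading chromosome label in column 1 is kept as
    the SNP's chromosome.  Pedigree fields, absent from the format, come
    from a sample file and/or a pedinfo table."""
    snps, triplets = [], []
    n_samples = None
    with open_source(gens) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 8:
                raise MalformedLine(ln, "gens row needs 5 id columns + triplets")
            if (len(tok) - 5) % 3 != 0:
                raise TripletCountMismatch(
                    f"line {ln}: {len(tok) - 5} probability columns not divisible by 3")
            ns = (len(tok) - 5) // 3
            if n_samples is None:
                n_samples = ns
            elif ns != n_samples:
                raise InconsistentColumnCount(ln, "gens rows disagree on sample count")
            chrom = tok[0] if _looks_like_chrom(tok[0]) else "0"
            snps.append(SnpRecord(chrom, tok[1], 0.0, int(tok[2]), tok[3], tok[4]))
            triplets.append([float(t) for t in tok[5:]])
    n_samples = n_samples or 0
    probs = (np.array(triplets).reshape(len(snps), n_samples, 3)
             if snps else np.zeros((0, 0, 3)))
    if sample is not None:
        samples = read_sample(sample)
        if len(samples) != n_samples:
            raise OrientationMismatch(
                f"sample file lists {len(samples)} ids, gens carries {n_samples}")
    else:
        samples = [SampleRecord(f"S{j+1}", f"S{j+1}") for j in range(n_samples)]
    ds = Dataset(snps, samples, GenotypeProbabilities(probs), source_format="impute-gens")
    return _apply_side_tables(ds, snpinfo, pedinfo)


def _apply_side_tables(ds: Dataset, snpinfo, pedinfo) -> Dataset:
    if snpinfo is not None or pedinfo is not None:
        from .manage import update_info
        ds = update_info(ds, snpinfo=snpinfo, pedinfo=pedinfo,
                         pedinfo_by_position=all(s.fid.startswith("S") for s in ds.samples))
    return ds


def write_gens(dataset: Dataset, gens, sample=None) -> WriteReport:
    """Write IMPUTE gens (+ optional sample file).  Requires a probability
    payload and allele labels on every SNP."""
    if not isinstance(dataset.payload, GenotypeProbabilities):
        raise UnsupportedPayload("gens output requires a probability payload")
    for s in dataset.snps:
        if s.allele1 == "0" or s.allele2 == "0":
            raise MissingAlleleLabels(f"{s.snp_id} lacks allele labels")
    probs = dataset.payload.probs
    with open_sink(gens) as fh:
        for i, s in enumerate(dataset.snps):
            lead = s.chrom if s.chrom != "0" else s.snp_id
            row = [lead, s.snp_id, str(s.bp), s.allele1, s.allele2]
            row.extend(fmt_float(v) for v in probs[i].ravel())
            fh.write(" ".join(row) + "\n")
    rep = WriteReport(files={"gens": sink_name(gens)}, rows={"gens": dataset.n_snps})
    if sample is not None:
        write_snptest_sample(dataset.samples, None, sample)
        rep.files["sample"] = sink_name(sample)
        rep.rows["sample"] = dataset.n_samples
    rep.note_loss("pedigree fields beyond ids live in the sample/pedinfo files")
    return rep


# ---------------------------------------------------------------------------
# IMPUTE hap/legend and SHAPEIT haps (haplotypes collapse to genotypes)

_HAP_MISSING = {"?", "-", "NA", "."}


def _collapse_haplotypes(h_tokens, ln: int) -> list:
    """Pairs of 0/1 haplotype columns -> genotype codes (count of allele2)."""
    if len(h_tokens) % 2:
        raise InconsistentColumnCount(ln, "odd number of haplotype columns")
    codes = []
    for k in range(0, len(h_tokens), 2):
        a, b = h_tokens[k], h_tokens[k + 1]
        if a in _HAP_MISSING or b in _HAP_MISSING:
            codes.append(MISSING)
        else:
            codes.append(int(a) + int(b))
    return codes


def read_hap_legend(hap, legend, sample=None) -> Dataset:
    """IMPUTE reference panel: legend (header "id position a0 a1") plus hap
    rows of 0/1 alleles, two columns per individual.  Phase is dropped;
    haplotype pairs collapse to unordered genotypes."""
    snps = []
    with open_source(legend) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows or rows[0][0].lower() not in ("id", "rs", "rsid"):
        raise HeaderMismatch("legend file must have an id/position header row")
    for tok in rows[1:]:
        if len(tok) < 4:
            raise MalformedLine(len(snps) + 2, "legend row needs id, position, two alleles")
        snps.append(SnpRecord("0", tok[0], 0.0, int(tok[1]), tok[2], tok[3]))
    geno_rows = []
    with open_source(hap) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            geno_rows.append(_collapse_haplotypes(tok, ln))
    if len(geno_rows) != len(snps):
        raise InconsistentColumnCount(len(geno_rows), "hap/legend row counts differ")
    codes = (np.array(geno_rows, dtype=np.int8)
             if geno_rows else np.zeros((0, 0), np.int8))
    n_samples = codes.shape[1] if codes.size else 0
    if sample is not None:
        samples = read_sample(sample)
        if len(samples) != n_samples:
            raise OrientationMismatch("sample file and hap column counts differ")
    else:
        samples = [SampleRecord(f"S{j+1}", f"S{j+1}") for j in range(n_samples)]
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="impute-hap")


def read_shapeit(haps, sample) -> Dataset:
    """SHAPEIT phased output: haps rows "chrom id bp a1 a2" + haplotype
    pairs; phase is intentionally dropped on load."""
    snps, geno_rows = [], []
    with open_source(haps) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 7:
                raise MalformedLine(ln, "haps row needs 5 id columns + haplotypes")
            snps.append(SnpRecord(tok[0], tok[1], 0.0, int(tok[2]), tok[3], tok[4]))
            geno_rows.append(_collapse_haplotypes(tok[5:], ln))
    codes = (np.array(geno_rows, dtype=np.int8)
             if geno_rows else np.zeros((0, 0), np.int8))
    samples = read_sample(sample)
    if codes.size and codes.shape[1] != len(samples):
        raise OrientationMismatch("sample file and haps column counts differ")
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="shapeit")


# ---------------------------------------------------------------------------
# MaCH mldose / mlprob / mlgeno + info

def _mach_id(token: str, ln: int):
    fid, sep, iid = token.partition("->")
    if not sep:
        raise BadIdToken(f"line {ln}: MaCH id {token!r} lacks '->'")
    return fid, iid


def read_mach_info(source) -> pd.DataFrame:
    """MaCH info file: columns SNP, Al1, Al2, Freq1, MAF, Quality, Rsq."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise HeaderMismatch("empty MaCH info file")
    header = [h.lower() for h in rows[0]]
    required = ["snp", "al1", "al2"]
    if header[:3] != required:
        raise HeaderMismatch(f"MaCH info header must start SNP Al1 Al2, got {rows[0][:3]}")
    cols = {name: header.index(name) for name in header}
    recs = []
    for tok in rows[1:]:
        rec = {"snp_id": tok[cols["snp"]], "al1": tok[cols["al1"]], "al2": tok[cols["al2"]]}
        for src, dst in (("freq1", "freq1"), ("maf", "maf"),
                         ("quality", "quality"), ("rsq", "rsq")):
            if src in cols and tok[cols[src]] not in ("-", "NA"):
                rec[dst] = float(tok[cols[src]])
        recs.append(rec)
    return pd.DataFrame(recs)


def _mach_snps(info: pd.DataFrame) -> list:
    return [SnpRecord("0", r["snp_id"], 0.0, 0, r["al1"], r["al2"])
            for _, r in info.iterrows()]


def read_mach(info, mldose=None, mlprob=None, mlgeno=None,
              pedinfo: Optional[list] = None, snpinfo: Optional[list] = None) -> Dataset:
    """MaCH imputation output.  Exactly one of mldose/mlprob/mlgeno is read;
    the info file supplies SNP ids, the allele pair and quality metrics.
    Files are sample-major: one row per individual, ids "FID->IID", and the
    number of data columns must match the info row count."""
    q = read_mach_info(info)
    snps = _mach_snps(q)
    n_snps = len(snps)
    given = [x for x in (mldose, mlprob, mlgeno) if x is not None]
    if len(given) != 1:
        raise UnsupportedPayload("exactly one of mldose/mlprob/mlgeno must be given")

    samples, rows = [], []
    src, per_snp = (mldose, 1) if mldose else (mlprob, 2) if mlprob else (mlgeno, 1)
    with open_source(src) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            fid, iid = _mach_id(tok[0], ln)
            samples.append(SampleRecord(fid, iid))
            data = tok[2:]  # tok[1] is the ML_DOSE/ML_PROB/ML_GENO tag
            if len(data) != per_snp * n_snps:
                raise OrientationMismatch(
                    f"line {ln}: {len(data)} data columns for {n_snps} SNPs "
                    f"({per_snp} per SNP expected)")
            rows.append(data)

    quality_cols = [c for c in ("snp_id", "freq1", "maf", "quality", "rsq") if c in q.columns]
    quality = q[quality_cols].copy()

    if mldose:
        doses = np.array([[np.nan if t in ("NA", ".") else float(t) for t in r]
                          for r in rows], dtype=np.float64).T
        payload = DosageMatrix(doses if doses.size else np.zeros((n_snps, 0)),
                               np.ones(n_snps, dtype=np.int8))  # doses count Al1
    elif mlprob:
        n_samp = len(rows)
        probs = np.zeros((n_snps, n_samp, 3))
        for j, r in enumerate(rows):
            for i in range(n_snps):
                p1 = float(r[2 * i])       # P(Al1/Al1)
                p2 = float(r[2 * i + 1])   # P(Al1/Al2)
                probs[i, j] = (p1, p2, max(0.0, 1.0 - p1 - p2))
        payload = GenotypeProbabilities(probs)
    else:
        from .io_pedigree import AlleleRegistry, _genotype_pairs
        reg = AlleleRegistry(n_snps, known=[(s.allele1, s.allele2) for s in snps])
        codes = np.zeros((n_snps, len(rows)), dtype=np.int8)
        for j, r in enumerate(rows):
            pairs = _genotype_pairs(r, n_snps, j + 1)
            for i, (a, b) in enumerate(pairs):
                codes[i, j] = reg.code(i, a, b)
        payload = HardCallMatrix(codes)

    ds = Dataset(snps, samples, payload, source_format="mach",
                 imputation_quality=quality)
    return _apply_side_tables(ds, snpinfo, pedinfo)


def write_mach(dataset: Dataset, stem: str) -> WriteReport:
    """Write MaCH-style output under ``stem``: dosage payloads become
    .mldose, probabilities .mlprob, hard calls .mlgeno; all get a .info
    file (Quality/Rsq written as "-" when the dataset carries none)."""
    p = dataset.payload
    rep = WriteReport()
    info_path = f"{stem}.info"
    q = dataset.imputation_quality
    qual_by_id = {} if q is None else {r["snp_id"]: r for _, r in q.iterrows()}
    f1 = model.freq_allele1(dataset)
    with open_sink(info_path) as fh:
        fh.write("SNP\tAl1\tAl2\tFreq1\tMAF\tQuality\tRsq\n")
        for i, s in enumerate(dataset.snps):
            row = qual_by_id.get(s.snp_id)
            freq1 = row.get("freq1", np.nan) if row is not None else f1[i]
            if row is None or np.isnan(freq1):
                freq1 = f1[i]
            maf = min(freq1, 1 - freq1) if not np.isnan(freq1) else np.nan
            quality = row.get("quality", np.nan) if row is not None else np.nan
            rsq = row.get("rsq", np.nan) if row is not None else np.nan

            def cell(v):
                return "-" if v is None or (isinstance(v, float) and np.isnan(v)) else fmt_float(v)
            fh.write(f"{s.snp_id}\t{s.allele1}\t{s.allele2}\t{cell(freq1)}\t"
                     f"{cell(maf)}\t{cell(quality)}\t{cell(rsq)}\n")
    rep.files["info"] = info_path
    rep.rows["info"] = dataset.n_snps

    if isinstance(p, DosageMatrix):
        # MaCH doses count Al1 (= allele1); re-express if needed
        doses = np.where(p.ref_slot[:, None] == 1, p.doses, 2.0 - p.doses)
        path = f"{stem}.mldose"
        with open_sink(path) as fh:
            for j, s in enumerate(dataset.samples):
                vals = " ".join("NA" if np.isnan(v) else fmt_float(v) for v in doses[:, j])
                fh.write(f"{s.fid}->{s.iid} ML_DOSE {vals}\n")
        rep.files["mldose"] = path
        rep.rows["mldose"] = dataset.n_samples
    elif isinstance(p, GenotypeProbabilities):
        path = f"{stem}.mlprob"
        with open_sink(path) as fh:
            for j, s in enumerate(dataset.samples):
                vals = []
                for i in range(dataset.n_snps):
                    vals.append(fmt_float(p.probs[i, j, 0]))
                    vals.append(fmt_float(p.probs[i, j, 1]))
                fh.write(f"{s.fid}->{s.iid} ML_PROB " + " ".join(vals) + "\n")
        rep.files["mlprob"] = path
        rep.rows["mlprob"] = dataset.n_samples
    else:
        path = f"{stem}.mlgeno"
        from .io_pedigree import _geno_token
        with open_sink(path) as fh:
            for j, s in enumerate(dataset.samples):
                cells = [_geno_token(snp, p.codes[i, j], sep="/")
                         for i, snp in enumerate(dataset.snps)]
                fh.write(f"{s.fid}->{s.iid} ML_GENO " + " ".join(cells) + "\n")
        rep.files["mlgeno"] = path
        rep.rows["mlgeno"] = dataset.n_samples
    rep.note_loss("chromosome, cM, bp, sex and phenotype are not representable "
                  "in MaCH files (use snpinfo/pedinfo side tables)")
    return rep


# ---------------------------------------------------------------------------
# BEAGLE gprobs

def read_beagle_gprobs(source, pedinfo: Optional[list] = None,
                       snpinfo: Optional[list] = None) -> Dataset:
    """BEAGLE gprobs: header "marker alleleA alleleB" + 3 columns per
    sample, rows "rs a b pAA pAB pBB ..."."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows or rows[0][0].lower() != "marker":
        raise HeaderMismatch("gprobs file must start with a 'marker' header")
    header = rows[0]
    ids = header[3:]
    if len(ids) % 3:
        raise TripletCountMismatch("gprobs header must list each sample id three times")
    sample_ids = []
    for k in range(0, len(ids), 3):
        if not (ids[k] == ids[k + 1] == ids[k + 2]):
            raise HeaderMismatch("gprobs header triplet ids disagree")
        sample_ids.append(ids[k])
    n_samples = len(sample_ids)
    snps, triplets = [], []
    for ln, tok in enumerate(rows[1:], 2):
        if len(tok) != 3 + 3 * n_samples:
            raise InconsistentColumnCount(ln, "gprobs row column count mismatch")
        snps.append(SnpRecord("0", tok[0], 0.0, 0, tok[1], tok[2]))
        triplets.append([float(t) for t in tok[3:]])
    probs = (np.array(triplets).reshape(len(snps), n_samples, 3)
             if snps else np.zeros((0, n_samples, 3)))
    samples = [SampleRecord(sid, sid) for sid in sample_ids]
    ds = Dataset(snps, samples, GenotypeProbabilities(probs), source_format="beagle-gprobs")
    return _apply_side_tables(ds, snpinfo, pedinfo)


def write_beagle_gprobs(dataset: Dataset, sink) -> WriteReport:
    if not isinstance(dataset.payload, GenotypeProbabilities):
        raise UnsupportedPayload("gprobs output requires a probability payload")
    probs = dataset.payload.probs
    with open_sink(sink) as fh:
        fh.write("marker alleleA alleleB "
                 + " ".join(f"{s.iid} {s.iid} {s.iid}" for s in dataset.samples) + "\n")
        for i, s in enumerate(dataset.snps):
            row = [s.snp_id, s.allele1, s.allele2]
            row.extend(fmt_float(v) for v in probs[i].ravel())
            fh.write(" ".join(row) + "\n")
    rep = WriteReport(files={"gprobs": sink_name(sink)}, rows={"gprobs": dataset.n_snps})
    rep.note_loss("positions and pedigree fields are not representable in gprobs")
    return rep


# ---------------------------------------------------------------------------
# PLINK dosage

def read_plink_dosage(dosage, fam=None, map_=None) -> Dataset:
    """PLINK dosage (format=1): header "SNP A1 A2" + FID IID pairs, one dose
    of A1 per sample and row per SNP."""
    with open_source(dosage) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows or [t.upper() for t in rows[0][:3]] != ["SNP", "A1", "A2"]:
        raise HeaderMismatch("dosage header must start SNP A1 A2")
    ids = rows[0][3:]
    if len(ids) % 2:
        raise HeaderMismatch("dosage header must carry FID IID pairs")
    samples = [SampleRecord(ids[k], ids[k + 1]) for k in range(0, len(ids), 2)]
    n_samples = len(samples)
    snps, data = [], []
    for ln, tok in enumerate(rows[1:], 2):
        if len(tok) != 3 + n_samples:
            raise InconsistentColumnCount(ln, "dosage row column count mismatch")
        snps.append(SnpRecord("0", tok[0], 0.0, 0, tok[1], tok[2]))
        data.append([np.nan if t in ("NA", ".") else float(t) for t in tok[3:]])
    doses = np.array(data, dtype=np.float64) if data else np.zeros((0, n_samples))
    if fam is not None:
        from .io_plink_binary import read_fam
        fam_samples = read_fam(fam)
        by_key = {(s.fid, s.iid): s for s in fam_samples}
        samples = [by_key.get((s.fid, s.iid), s) for s in samples]
    if map_ is not None:
        from .io_pedigree import read_map
        by_id = {s.snp_id: s for s in read_map(map_)}
        for s in snps:
            if s.snp_id in by_id:
                m = by_id[s.snp_id]
                s.chrom, s.cm, s.bp = m.chrom, m.cm, m.bp
    payload = DosageMatrix(doses, np.ones(len(snps), dtype=np.int8))
    return Dataset(snps, samples, payload, source_format="plink-dosage")


def write_plink_dosage(dataset: Dataset, sink) -> WriteReport:
    """Doses are written as counts of A1 (= allele1), converting from the
    dataset's payload as needed."""
    if isinstance(dataset.payload, HardCallMatrix):
        raise UnsupportedPayload(
            "plink-dosage requires probabilities or dosage; convert hard calls first")
    conv = (dataset if isinstance(dataset.payload, DosageMatrix)
            else model.convert_payload(dataset, "dosage",
                                       model.ConversionPolicy(ref_policy="first")))
    dm = conv.payload
    doses = np.where(dm.ref_slot[:, None] == 1, dm.doses, 2.0 - dm.doses)
    with open_sink(sink) as fh:
        fh.write("SNP A1 A2 " + " ".join(f"{s.fid} {s.iid}" for s in dataset.samples) + "\n")
        for i, s in enumerate(dataset.snps):
            vals = " ".join("NA" if np.isnan(v) else fmt_float(v) for v in doses[i])
            fh.write(f"{s.snp_id} {s.allele1} {s.allele2} {vals}\n")
    rep = WriteReport(files={"dosage": sink_name(sink)}, rows={"dosage": dataset.n_snps})
    rep.note_loss("positions and pedigree fields live in the map/fam side files")
    return rep


# ---------------------------------------------------------------------------
# quality tables

def read_quality(dialect_id: str, source) -> pd.DataFrame:
    """Imputation-quality table; one row per SNP.

    ``mach-info`` populates freq1/maf/quality/rsq; ``impute-info``
    populates freq1/info/certainty.  Metrics a dialect does not report are
    absent from the frame, never defaulted to 0.
    """
    if dialect_id == "mach-info":
        df = read_mach_info(source)
        return df.drop(columns=[c for c in ("al1", "al2") if c in df.columns])
    if dialect_id == "impute-info":
        with open_source(source) as fh:
            rows = [line.split() for line in fh if line.strip()]
        if not rows:
            raise HeaderMismatch("empty info file")
        header = [h.lower() for h in rows[0]]
        if "info" not in header:
            raise HeaderMismatch("IMPUTE info file must have an 'info' column")
        idx = {h: k for k, h in enumerate(header)}
        id_col = next((idx[c] for c in ("rs_id", "rsid", "snp_id", "id") if c in idx), None)
        if id_col is None:
            raise HeaderMismatch("IMPUTE info file lacks an id column")
        recs = []
        for tok in rows[1:]:
            rec = {"snp_id": tok[id_col], "info": float(tok[idx["info"]])}
            if "exp_freq_a1" in idx:
                rec["freq1"] = float(tok[idx["exp_freq_a1"]])
            if "certainty" in idx:
                rec["certainty"] = float(tok[idx["certainty"]])
            recs.append(rec)
        return pd.DataFrame(recs)
    raise HeaderMismatch(f"unknown quality dialect {dialect_id!r}")


# ---------------------------------------------------------------------------
# VCF export

_GT = {MISSING: "./.", model.HOM1: "0/0", model.HET: "0/1", model.HOM2: "1/1"}


def write_vcf(dataset: Dataset, sink) -> WriteReport:
    """Export as VCF 4.2 with REF = allele1 and ALT = allele2.

    No genome-reference check is performed: REF is simply the dataset's
    first allele.  Hard calls export GT, dosages DS (ALT-allele dose) and
    probability payloads DS + GP.
    """
    for s in dataset.snps:
        if s.bp <= 0:
            raise MissingPosition(f"{s.snp_id} has no base-pair position")
    p = dataset.payload
    if isinstance(p, HardCallMatrix):
        fmt = "GT"
    elif isinstance(p, DosageMatrix):
        fmt = "DS"
    else:
        fmt = "DS:GP"

    with open_sink(sink) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genoconv\n")
        for chrom in dict.fromkeys(s.chrom for s in dataset.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        if "GT" in fmt:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "DS" in fmt:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Dosage of the ALT allele">\n')
        if "GP" in fmt:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype probabilities (REF/REF, REF/ALT, ALT/ALT)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.iid for s in dataset.samples) + "\n")
        for i, s in enumerate(dataset.snps):
            cells = []
            for j in range(dataset.n_samples):
                if isinstance(p, HardCallMatrix):
                    cells.append(_GT[int(p.codes[i, j])])
                elif isinstance(p, DosageMatrix):
                    v = p.doses[i, j]
                    if np.isnan(v):
                        cells.append(".")
                    else:
                        alt = v if p.ref_slot[i] == 2 else 2.0 - v
                        cells.append(fmt_float(alt))
                else:
                    paa, pab, pbb = p.probs[i, j]
                    if paa == pab == pbb == 0.0:
                        cells.append(".:.")
                    else:
                        ds_ = pab + 2.0 * pbb
                        cells.append(f"{fmt_float(ds_)}:"
                                     f"{fmt_float(paa)},{fmt_float(pab)},{fmt_float(pbb)}")
            fh.write(f"{s.chrom}\t{s.bp}\t{s.snp_id}\t{s.allele1}\t{s.allele2}\t"
                     f".\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")
    return WriteReport(files={"vcf": sink_name(sink)}, rows={"vcf": dataset.n_snps})


# ---------------------------------------------------------------------------
# dispatchers mirroring io_pedigree's surface

def parse_probfile(dialect_id: str, sources: dict, pedinfo: Optional[list] = None,
                   snpinfo: Optional[list] = None) -> Dataset:
    """Dispatch to the reader of an imputation-format dialect."""
    if dialect_id == "impute-gens":
        return read_gens(sources["gens"], sources.get("sample"), pedinfo, snpinfo)
    if dialect_id == "impute-hap":
        ds = read_hap_legend(sources["hap"], sources["legend"], sources.get("sample"))
        return _apply_side_tables(ds, snpinfo, pedinfo)
    if dialect_id == "shapeit":
        ds = read_shapeit(sources["haps"], sources["sample"])
        return _apply_side_tables(ds, snpinfo, pedinfo)
    if dialect_id == "mach":
        return read_mach(sources["info"], mldose=sources.get("mldose"),
                         mlprob=sources.get("mlprob"), mlgeno=sources.get("mlgeno"),
                         pedinfo=pedinfo, snpinfo=snpinfo)
    if dialect_id == "beagle-gprobs":
        return read_beagle_gprobs(sources["gprobs"], pedinfo, snpinfo)
    if dialect_id == "plink-dosage":
        ds = read_plink_dosage(sources["dosage"], sources.get("fam"), sources.get("map"))
        return _apply_side_tables(ds, snpinfo, pedinfo)
    raise HeaderMismatch(f"unknown imputation dialect {dialect_id!r}")


def render_probfile(dataset: Dataset, dialect_id: str, sinks: dict,
                    options: Optional[dict] = None) -> WriteReport:
    """Dispatch to the writer of an imputation-format dialect."""
    options = options or {}
    if dialect_id == "impute-gens":
        return write_gens(dataset, sinks["gens"], sinks.get("sample"))
    if dialect_id == "mach":
        return write_mach(dataset, sinks["stem"])
    if dialect_id == "beagle-gprobs":
        return write_beagle_gprobs(dataset, sinks["gprobs"])
    if dialect_id == "plink-dosage":
        return write_plink_dosage(dataset, sinks["dosage"])
    if dialect_id == "snptest":
        rep = write_gens(dataset, sinks["gen"])
        write_snptest_sample(dataset.samples, options.get("covars"), sinks["sample"])
        rep.files["sample"] = sink_name(sinks["sample"])
        rep.rows["sample"] = dataset.n_samples
        return rep
    if dialect_id == "vcf":
        return write_vcf(dataset, sinks["vcf"])
    raise HeaderMismatch(f"unknown imputation dialect {dialect_id!r}")
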