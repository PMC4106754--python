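"""Readers and writers for text hard-call genotype formats.

Covered dialects: PLINK ped/map, MERLIN/MaCH ped/dat, EIGENSOFT
geno/snp/ind, HAPLOVIEW linkage ped + marker info, BEAGLE genotype files,
BIMBAM mean-genotype + pos, reference-allele count matrices ("rgeno" and
the r / r-dose exports), PLINK raw recodeA/recodeAD (read), and PHASE /
fastPHASE inputs (write).  All paths ending ``.gz`` are read and written
compressed, transparently.

Writers use a single space as separator and "\\n" line endings on every
platform, so byte-level round trips are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import model
from ._io_util import WriteReport, fmt_float, open_sink, open_source, sink_name
from .errors import (
    CountOutOfRange,
    HeaderMismatch,
    InconsistentColumnCount,
    MalformedLine,
    RoleMissing,
    UnknownAlleleToken,
    UnsupportedPayload,
    UnwritableAllele,
)
from .model import (
    MISSING,
    Dataset,
    DosageMatrix,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)

_MISSING_ALLELES = {"0", "?", "N", "."}
_NA_TOKENS = {"NA", "na", "?", ".", "-"}


@dataclass
class FormatDialect:
    """Registry entry describing one file-format family."""

    dialect_id: str
    file_roles: dict            # role -> filename suffix pattern
    payload_kind: str           # "hard-calls" | "counts"
    orientation: str            # "sample-major" | "snp-major"
    required_roles: tuple
    readable: bool = True
    writable: bool = True


DIALECTS = {
    d.dialect_id: d for d in [
        FormatDialect("plink-ped", {"ped": ".ped", "map": ".map"},
                      "hard-calls", "sample-major", ("ped", "map")),
        FormatDialect("merlin", {"ped": ".ped", "dat": ".dat"},
                      "hard-calls", "sample-major", ("ped", "dat")),
        FormatDialect("eigensoft", {"geno": ".geno", "snp": ".snp", "ind": ".ind"},
                      "hard-calls", "snp-major", ("geno", "snp", "ind")),
        FormatDialect("haploview", {"ped": ".ped", "info": ".info"},
                      "hard-calls", "sample-major", ("ped", "info")),
        FormatDialect("beagle", {"bgl": ".bgl"},
                      "hard-calls", "snp-major", ("bgl",)),
        FormatDialect("bimbam", {"wbg": ".wbg", "pos": ".pos"},
                      "counts", "snp-major", ("wbg",)),
        FormatDialect("rgeno", {"rgeno": ".rgeno", "snpinfo": ".snpinfo"},
                      "counts", "sample-major", ("rgeno",)),
        FormatDialect("recodeA-raw", {"raw": ".raw"},
                      "counts", "sample-major", ("raw",)),
        FormatDialect("phase", {"inp": ".phase.inp"},
                      "hard-calls", "sample-major", ("inp",), readable=False),
        FormatDialect("fastphase", {"inp": ".fastphase.inp"},
                      "hard-calls", "sample-major", ("inp",), readable=False),
    ]
}


# ---------------------------------------------------------------------------
# allele bookkeeping

class AlleleRegistry:
    """Assigns allele slots per SNP in order of first appearance.

    Readers of formats that do not declare the allele pair up front (ped
    files) use this to build SnpRecord.allele1/allele2 deterministically.
    """

    def __init__(self, n_snps: int, known: Optional[list] = None):
        # known: list of (allele1, allele2) from an annotation file, "0" = open slot
        self.slots = [[None, None] for _ in range(n_snps)]
        if known is not None:
            for i, (a1, a2) in enumerate(known):
                if a1 not in _MISSING_ALLELES:
                    self.slots[i][0] = a1
                if a2 not in _MISSING_ALLELES:
                    self.slots[i][1] = a2

    def _slot(self, i: int, allele: str) -> int:
        s = self.slots[i]
        if allele == s[0]:
            return 0
        if allele == s[1]:
            return 1
        if s[0] is None:
            s[0] = allele
            return 0
        if s[1] is None:
            s[1] = allele
            return 1
        raise UnknownAlleleToken(
            f"SNP index {i}: third allele {allele!r} (have {s[0]!r}/{s[1]!r})")

    def code(self, i: int, a: str, b: str) -> int:
        """Genotype code (count of allele2) for an allele pair; any missing
        allele makes the whole genotype missing."""
        if a in _MISSING_ALLELES or b in _MISSING_ALLELES:
            return MISSING
        return self._slot(i, a) + self._slot(i, b)

    def pair(self, i: int):
        s = self.slots[i]
        return (s[0] or "0", s[1] or "0")


def _genotype_pairs(tokens: list, n_snps: int, line_no: int) -> list:
    """Normalise ped genotype tokens to a list of (a, b) pairs.

    Accepts two whitespace tokens per genotype ("A G") or one slashed token
    per genotype ("A/G"); the two shapes may not be mixed on one line.
    """
    if len(tokens) == 2 * n_snps:
        return [(tokens[2 * i], tokens[2 * i + 1]) for i in range(n_snps)]
    if len(tokens) == n_snps:
        pairs = []
        for t in tokens:
            if "/" in t:
                a, _, b = t.partition("/")
            elif t in _MISSING_ALLELES:
                a = b = "0"
            elif len(t) == 2:
                a, b = t[0], t[1]
            else:
                raise MalformedLine(line_no, f"cannot split genotype token {t!r}")
            pairs.append((a, b))
        return pairs
    raise InconsistentColumnCount(
        line_no, f"{len(tokens)} genotype tokens for {n_snps} SNPs")


def _geno_token(snp: SnpRecord, code: int, sep: str = " ") -> str:
    if code == MISSING:
        return f"0{sep}0"
    a1, a2 = snp.allele1, snp.allele2
    if code == model.HOM1:
        return f"{a1}{sep}{a1}"
    if code == model.HET:
        return f"{a1}{sep}{a2}"
    return f"{a2}{sep}{a2}"


def _fmt_cm(cm: float) -> str:
    return str(int(cm)) if float(cm).is_integer() else fmt_float(cm)


# ---------------------------------------------------------------------------
# PLINK ped/map  (HAPLOVIEW shares the ped reader)

def read_map(source) -> list:
    snps = []
    with open_source(source) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (3, 4):
                raise InconsistentColumnCount(ln, f"map line has {len(tok)} columns")
            if len(tok) == 3:  # chrom id bp (cM column omitted)
                chrom, sid, bp = tok
                cm = 0.0
            else:
                chrom, sid, cm, bp = tok
            snps.append(SnpRecord(chrom, sid, float(cm), int(bp), "0", "0"))
    return snps


def _read_linkage_ped(source, n_snps: int):
    """Shared ped-body reader: 6 pedigree columns + genotypes."""
    samples, rows = [], []
    reg = AlleleRegistry(n_snps)
    with open_source(source) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6:
                raise MalformedLine(ln, "fewer than 6 pedigree columns")
            fid, iid, pat, mat, sex, pheno = tok[:6]
            samples.append(SampleRecord(fid, iid, pat, mat, int(sex), pheno))
            pairs = _genotype_pairs(tok[6:], n_snps, ln)
            rows.append([reg.code(i, a, b) for i, (a, b) in enumerate(pairs)])
    codes = np.array(rows, dtype=np.int8).T if rows else np.zeros((n_snps, 0), np.int8)
    return samples, codes, reg


def read_ped_map(ped, map_) -> Dataset:
    """PLINK text format: ped (one row per individual) + map (one per SNP)."""
    snps = read_map(map_)
    samples, codes, reg = _read_linkage_ped(ped, len(snps))
    for i, snp in enumerate(snps):
        snp.allele1, snp.allele2 = reg.pair(i)
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="plink-ped")


def _require_hardcalls(dataset: Dataset) -> HardCallMatrix:
    if not isinstance(dataset.payload, HardCallMatrix):
        raise UnsupportedPayload(
            f"{dataset.payload.kind} payload cannot be written as hard calls; "
            "convert first (best-guess threshold or rounding policy)")
    return dataset.payload


def write_ped_map(dataset: Dataset, ped, map_) -> WriteReport:
    p = _require_hardcalls(dataset)
    rep = WriteReport()
    with open_sink(map_) as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom} {s.snp_id} {_fmt_cm(s.cm)} {s.bp}\n")
    with open_sink(ped) as fh:
        for j, s in enumerate(dataset.samples):
            cells = [_geno_token(snp, p.codes[i, j])
                     for i, snp in enumerate(dataset.snps)]
            fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} {s.phenotype} "
                     + " ".join(cells) + "\n")
    rep.files = {"ped": sink_name(ped), "map": sink_name(map_)}
    rep.rows = {"ped": dataset.n_samples, "map": dataset.n_snps}
    return rep


# ---------------------------------------------------------------------------
# MERLIN / MaCH ped + dat

def read_merlin(ped, dat, snpinfo: Optional[list] = None) -> Dataset:
    """MERLIN (MaCH) ped/dat.  dat lines "M <snp>" declare markers; other
    dat record types (traits, covariates) are skipped with a warning note.
    The ped body is fid iid pat mat sex then one genotype per marker
    ("A/G" or two tokens).  A snpinfo table, when given, anchors allele
    slots to its allele order and restores the chromosome/position fields
    the format cannot carry."""
    snp_ids, skipped = [], []
    with open_source(dat) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "M":
                if len(tok) < 2:
                    raise MalformedLine(ln, "dat M line lacks a marker name")
                snp_ids.append(tok[1])
            else:
                skipped.append(tok[0])
    if skipped:
        import warnings
        warnings.warn(f"skipped {len(skipped)} non-marker dat records "
                      f"(types {sorted(set(skipped))})")
    n_snps = len(snp_ids)
    known = None
    if snpinfo is not None:
        by_id = {s.snp_id: s for s in snpinfo}
        known = [(by_id[sid].allele1, by_id[sid].allele2) if sid in by_id else ("0", "0")
                 for sid in snp_ids]
    samples, rows = [], []
    reg = AlleleRegistry(n_snps, known=known)
    with open_source(ped) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 5:
                raise MalformedLine(ln, "fewer than 5 pedigree columns")
            fid, iid, pat, mat, sex = tok[:5]
            samples.append(SampleRecord(fid, iid, pat, mat, int(sex)))
            pairs = _genotype_pairs(tok[5:], n_snps, ln)
            rows.append([reg.code(i, a, b) for i, (a, b) in enumerate(pairs)])
    codes = np.array(rows, dtype=np.int8).T if rows else np.zeros((n_snps, 0), np.int8)
    snps = [SnpRecord("0", sid, 0.0, 0, *reg.pair(i)) for i, sid in enumerate(snp_ids)]
    ds = Dataset(snps, samples, HardCallMatrix(codes), source_format="merlin")
    if snpinfo is not None:
        from .manage import update_info
        ds = update_info(ds, snpinfo=snpinfo)
    return ds


def write_merlin(dataset: Dataset, ped, dat) -> WriteReport:
    p = _require_hardcalls(dataset)
    rep = WriteReport()
    with open_sink(dat) as fh:
        for s in dataset.snps:
            fh.write(f"M {s.snp_id}\n")
    with open_sink(ped) as fh:
        for j, s in enumerate(dataset.samples):
            cells = [_geno_token(snp, p.codes[i, j], sep="/")
                     for i, snp in enumerate(dataset.snps)]
            fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} " + " ".join(cells) + "\n")
    rep.files = {"ped": sink_name(ped), "dat": sink_name(dat)}
    rep.rows = {"ped": dataset.n_samples, "dat": dataset.n_snps}
    rep.note_loss("phenotype, chromosome, cM and bp are not representable in MERLIN ped/dat")
    return rep


# ---------------------------------------------------------------------------
# EIGENSOFT geno / snp / ind

_EIG_SEX = {0: "U", 1: "M", 2: "F"}
_EIG_SEX_BACK = {"U": 0, "M": 1, "F": 2}


def read_eigensoft(geno, snp, ind) -> Dataset:
    """EIGENSOFT triple: geno has one row per SNP, one digit per sample with
    the count of allele1 ('9' missing); snp carries the annotation; ind has
    id, sex letter and a status/group column ("-99" = missing)."""
    snps = []
    with open_source(snp) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise MalformedLine(ln, "snp line needs id, chrom, cM, bp")
            a1 = tok[4] if len(tok) > 4 else "0"
            a2 = tok[5] if len(tok) > 5 else "0"
            snps.append(SnpRecord(tok[1], tok[0], float(tok[2]), int(tok[3]), a1, a2))
    samples = []
    with open_source(ind) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            iid = tok[0]
            sex = _EIG_SEX_BACK.get(tok[1], 0) if len(tok) > 1 else 0
            status = tok[2] if len(tok) > 2 else "-99"
            pheno = {"Case": "2", "Control": "1", "-99": model.MISSING_PHENO}.get(status, status)
            samples.append(SampleRecord(iid, iid, "0", "0", sex, pheno))
    codes = np.zeros((len(snps), len(samples)), dtype=np.int8)
    with open_source(geno) as fh:
        i = -1
        for ln, line in enumerate(fh, 1):
            row = line.strip()
            if not row:
                continue
            i += 1
            if i >= len(snps):
                raise InconsistentColumnCount(ln, "more geno rows than snp records")
            if len(row) != len(samples):
                raise InconsistentColumnCount(
                    ln, f"geno row has {len(row)} characters for {len(samples)} samples")
            for j, ch in enumerate(row):
                if ch == "9":
                    codes[i, j] = MISSING
                elif ch in "012":
                    codes[i, j] = 2 - int(ch)  # stored digit counts allele1
                else:
                    raise MalformedLine(ln, f"invalid geno character {ch!r}")
        if i + 1 != len(snps):
            raise InconsistentColumnCount(i + 1, "fewer geno rows than snp records")
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="eigensoft")


def write_eigensoft(dataset: Dataset, geno, snp, ind,
                    group_labels: Optional[dict] = None) -> WriteReport:
    p = _require_hardcalls(dataset)
    rep = WriteReport()
    with open_sink(snp) as fh:
        for s in dataset.snps:
            fh.write(f"{s.snp_id} {s.chrom} {_fmt_cm(s.cm)} {s.bp} {s.allele1} {s.allele2}\n")
    with open_sink(ind) as fh:
        for s in dataset.samples:
            if group_labels and s.iid in group_labels:
                status = group_labels[s.iid]
            elif s.phenotype == "2":
                status = "Case"
            elif s.phenotype == "1":
                status = "Control"
            else:
                status = "-99"
            fh.write(f"{s.iid} {_EIG_SEX[s.sex]} {status}\n")
    digit = {MISSING: "9", model.HOM1: "2", model.HET: "1", model.HOM2: "0"}
    with open_sink(geno) as fh:
        for i in range(dataset.n_snps):
            fh.write("".join(digit[int(c)] for c in p.codes[i]) + "\n")
    rep.files = {"geno": sink_name(geno), "snp": sink_name(snp), "ind": sink_name(ind)}
    rep.rows = {"geno": dataset.n_snps, "snp": dataset.n_snps, "ind": dataset.n_samples}
    rep.note_loss("fid, pat and mat are not representable in EIGENSOFT ind files")
    return rep


# ---------------------------------------------------------------------------
# HAPLOVIEW linkage ped + marker info

def read_haploview(ped, info) -> Dataset:
    snps = []
    with open_source(info) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 2:
                raise MalformedLine(ln, "info line needs marker name and bp")
            snps.append(SnpRecord("0", tok[0], 0.0, int(tok[1]), "0", "0"))
    samples, codes, reg = _read_linkage_ped(ped, len(snps))
    for i, snp in enumerate(snps):
        snp.allele1, snp.allele2 = reg.pair(i)
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="haploview")


def _write_ped_body(dataset: Dataset, ped) -> None:
    p = _require_hardcalls(dataset)
    with open_sink(ped) as fh:
        for j, s in enumerate(dataset.samples):
            cells = [_geno_token(snp, p.codes[i, j]) for i, snp in enumerate(dataset.snps)]
            fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} {s.phenotype} "
                     + " ".join(cells) + "\n")


def write_haploview(dataset: Dataset, ped, info) -> WriteReport:
    """HAPLOVIEW needs a linkage ped plus a 2-column marker/bp info file."""
    _write_ped_body(dataset, ped)
    with open_sink(info) as fh:
        for s in dataset.snps:
            fh.write(f"{s.snp_id} {s.bp}\n")
    rep = WriteReport(files={"ped": sink_name(ped), "info": sink_name(info)},
                      rows={"ped": dataset.n_samples, "info": dataset.n_snps})
    rep.note_loss("chromosome and cM are not representable in HAPLOVIEW info files")
    return rep


# ---------------------------------------------------------------------------
# BEAGLE genotype file (unphased, BEAGLE 3 text layout)

def read_beagle(bgl) -> Dataset:
    """BEAGLE genotype file: header row "I id s1 s1 s2 s2 ...", marker rows
    "M rs1 A G A A ...".  Non-marker data rows (e.g. "A" affection rows)
    are skipped."""
    samples, snp_ids, geno_rows = [], [], []
    with open_source(bgl) as fh:
        header = None
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if header is None:
                if tok[0] != "I":
                    raise HeaderMismatch(f"expected BEAGLE header row 'I ...', got {tok[0]!r}")
                ids = tok[2:]
                if len(ids) % 2:
                    raise HeaderMismatch("BEAGLE header must list each sample id twice")
                for k in range(0, len(ids), 2):
                    if ids[k] != ids[k + 1]:
                        raise HeaderMismatch(
                            f"sample id columns disagree: {ids[k]!r} vs {ids[k+1]!r}")
                    samples.append(SampleRecord(ids[k], ids[k], "0", "0", 0))
                header = tok
                continue
            if tok[0] != "M":
                continue
            if len(tok) != 2 + 2 * len(samples):
                raise InconsistentColumnCount(
                    ln, f"marker row has {len(tok)} columns, expected {2 + 2*len(samples)}")
            snp_ids.append(tok[1])
            geno_rows.append(tok[2:])
    if header is None:
        raise HeaderMismatch("empty BEAGLE genotype file")
    n_snps = len(snp_ids)
    reg = AlleleRegistry(n_snps)
    codes = np.zeros((n_snps, len(samples)), dtype=np.int8)
    for i, row in enumerate(geno_rows):
        for j in range(len(samples)):
            codes[i, j] = reg.code(i, row[2 * j], row[2 * j + 1])
    snps = [SnpRecord("0", sid, 0.0, 0, *reg.pair(i)) for i, sid in enumerate(snp_ids)]
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="beagle")


def write_beagle(dataset: Dataset, bgl) -> WriteReport:
    p = _require_hardcalls(dataset)
    with open_sink(bgl) as fh:
        fh.write("I id " + " ".join(f"{s.iid} {s.iid}" for s in dataset.samples) + "\n")
        for i, snp in enumerate(dataset.snps):
            cells = [_geno_token(snp, p.codes[i, j]) for j in range(dataset.n_samples)]
            fh.write(f"M {snp.snp_id} " + " ".join(cells) + "\n")
    rep = WriteReport(files={"bgl": sink_name(bgl)}, rows={"bgl": dataset.n_snps + 1})
    rep.note_loss("pedigree and SNP position fields are not representable in "
                  "BEAGLE genotype files")
    return rep


# ---------------------------------------------------------------------------
# BIMBAM mean genotype + pos

def _split_commas(line: str) -> list:
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip()]
    return line.split()


def read_bimbam(wbg, pos=None) -> Dataset:
    """BIMBAM mean-genotype file: per SNP a row "rs, a1, a2, d1, d2, ..."
    with expected counts of the first listed allele; optional pos file
    "rs, bp, chrom".  Delimiter may be comma or whitespace."""
    snp_ids, pairs, rows = [], [], []
    with open_source(wbg) as fh:
        for ln, line in enumerate(fh, 1):
            tok = _split_commas(line)
            if not tok:
                continue
            if len(tok) < 3:
                raise MalformedLine(ln, "mean-genotype row needs snp, two alleles, doses")
            snp_ids.append(tok[0])
            pairs.append((tok[1], tok[2]))
            rows.append([np.nan if t in _NA_TOKENS else float(t) for t in tok[3:]])
    n_samples = len(rows[0]) if rows else 0
    for ln, r in enumerate(rows, 1):
        if len(r) != n_samples:
            raise InconsistentColumnCount(ln, "ragged mean-genotype matrix")
    doses = np.array(rows, dtype=np.float64) if rows else np.zeros((0, 0))
    with np.errstate(invalid="ignore"):
        if ((doses < 0) | (doses > 2)).any():
            raise CountOutOfRange("mean genotype outside [0, 2]")
    snps = [SnpRecord("0", sid, 0.0, 0, a1, a2)
            for sid, (a1, a2) in zip(snp_ids, pairs)]
    if pos is not None:
        by_id = {s.snp_id: s for s in snps}
        with open_source(pos) as fh:
            for ln, line in enumerate(fh, 1):
                tok = _split_commas(line)
                if not tok:
                    continue
                if tok[0] in by_id:
                    if len(tok) > 1:
                        by_id[tok[0]].bp = int(tok[1])
                    if len(tok) > 2:
                        by_id[tok[0]].chrom = tok[2]
    samples = [SampleRecord(f"S{j+1}", f"S{j+1}") for j in range(n_samples)]
    payload = DosageMatrix(doses, np.ones(len(snps), dtype=np.int8))
    return Dataset(snps, samples, payload, source_format="bimbam")


def write_bimbam(dataset: Dataset, wbg, pos) -> WriteReport:
    """Mean-genotype values are expected counts of allele1 (the first listed
    allele), derived from whatever payload the dataset carries."""
    conv = model.convert_payload(dataset, "dosage", model.ConversionPolicy(ref_policy="first")) \
        if not isinstance(dataset.payload, DosageMatrix) else dataset
    dm = conv.payload
    doses = np.where(dm.ref_slot[:, None] == 1, dm.doses, 2.0 - dm.doses)
    with open_sink(wbg) as fh:
        for i, s in enumerate(dataset.snps):
            vals = ", ".join("NA" if np.isnan(v) else fmt_float(v) for v in doses[i])
            fh.write(f"{s.snp_id}, {s.allele1}, {s.allele2}, {vals}\n")
    with open_sink(pos) as fh:
        for s in dataset.snps:
            fh.write(f"{s.snp_id}, {s.bp}, {s.chrom}\n")
    rep = WriteReport(files={"wbg": sink_name(wbg), "pos": sink_name(pos)},
                      rows={"wbg": dataset.n_snps, "pos": dataset.n_snps})
    rep.note_loss("pedigree fields are not representable in BIMBAM files")
    return rep


# ---------------------------------------------------------------------------
# reference-allele count matrices: rgeno read, r / r-dose write

def read_rgeno(rgeno, snpinfo: Optional[list] = None, transposed: bool = False) -> Dataset:
    """Count matrix: header row of SNP ids, first column sample ids, cells
    counts (0/1/2) of the reference allele (= allele1 of the snpinfo
    table when given).  ``transposed`` swaps the roles of rows/columns."""
    with open_source(rgeno) as fh:
        lines = [line.split() for line in fh if line.strip()]
    if not lines:
        raise HeaderMismatch("empty count-matrix file")
    header = lines[0]
    col_ids = header[1:]
    row_ids, rows = [], []
    for ln, tok in enumerate(lines[1:], 2):
        if len(tok) != len(col_ids) + 1:
            raise InconsistentColumnCount(ln, "ragged count matrix")
        row_ids.append(tok[0])
        vals = []
        for t in tok[1:]:
            if t in _NA_TOKENS:
                vals.append(np.nan)
            else:
                v = float(t)
                if not (0.0 <= v <= 2.0):
                    raise CountOutOfRange(f"line {ln}: count {t} outside [0, 2]")
                vals.append(v)
        rows.append(vals)
    mat = np.array(rows, dtype=np.float64) if rows else np.zeros((0, len(col_ids)))
    if transposed:
        snp_ids, sample_ids, doses = row_ids, col_ids, mat
    else:
        snp_ids, sample_ids, doses = col_ids, row_ids, mat.T

    info_by_id = {s.snp_id: s for s in snpinfo} if snpinfo else {}
    snps = []
    for sid in snp_ids:
        if sid in info_by_id:
            snps.append(info_by_id[sid].copy())
        else:
            snps.append(SnpRecord("0", sid, 0.0, 0, "0", "0"))
    samples = []
    for tok in sample_ids:
        fid, _, iid = tok.partition("->")
        if not iid:
            fid = iid = tok
        samples.append(SampleRecord(fid, iid))
    payload = DosageMatrix(doses, np.ones(len(snps), dtype=np.int8))
    return Dataset(snps, samples, payload, source_format="rgeno")


def write_r_matrix(dataset: Dataset, sink, dose: bool = False,
                   ref_policy: str = "minor", transpose: bool = False) -> WriteReport:
    """The r / r-dose export: a plain text matrix of reference-allele counts
    (or expected doses), rows = samples, columns = SNPs, with a simple
    header of SNP ids and a leading sample-id column.  ``transpose`` writes
    SNPs as rows instead.  Re-importable through :func:`read_rgeno`."""
    conv = model.convert_payload(dataset, "dosage", model.ConversionPolicy(ref_policy=ref_policy)) \
        if not isinstance(dataset.payload, DosageMatrix) else dataset
    dm = conv.payload

    def cell(v):
        if np.isnan(v):
            return "NA"
        return fmt_float(v) if dose else str(int(round(v)))

    with open_sink(sink) as fh:
        if transpose:
            fh.write("id " + " ".join(s.iid for s in dataset.samples) + "\n")
            for i, s in enumerate(dataset.snps):
                fh.write(s.snp_id + " " + " ".join(cell(v) for v in dm.doses[i]) + "\n")
            n_rows = dataset.n_snps
        else:
            fh.write("id " + " ".join(s.snp_id for s in dataset.snps) + "\n")
            for j, s in enumerate(dataset.samples):
                fh.write(s.iid + " " + " ".join(cell(dm.doses[i, j])
                                                for i in range(dataset.n_snps)) + "\n")
            n_rows = dataset.n_samples
    rep = WriteReport(files={"rgeno": sink_name(sink)}, rows={"rgeno": n_rows})
    rep.note_loss("SNP annotation lives in the companion snpinfo file, not the matrix")
    return rep


# ---------------------------------------------------------------------------
# PLINK raw (recodeA / recodeAD) read

def read_recodeA(raw) -> Dataset:
    """PLINK 1.x raw file: header FID IID PAT MAT SEX PHENOTYPE then one
    column per SNP named <snp>_<counted allele>; cells 0/1/2/NA (or real
    doses for dose-coded raw files).  Dominance (_HET) columns from
    recodeAD are recognised and dropped."""
    with open_source(raw) as fh:
        lines = [line.split() for line in fh if line.strip()]
    if not lines:
        raise HeaderMismatch("empty raw file")
    header = lines[0]
    if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
        raise HeaderMismatch("raw header must start FID IID PAT MAT SEX PHENOTYPE")
    keep_cols, snps = [], []
    for k, name in enumerate(header[6:], start=6):
        if name.endswith("_HET"):
            continue
        sid, _, allele = name.rpartition("_")
        if not sid:
            sid, allele = name, "0"
        keep_cols.append(k)
        snps.append(SnpRecord("0", sid, 0.0, 0, allele, "0"))
    samples, rows = [], []
    for ln, tok in enumerate(lines[1:], 2):
        if len(tok) != len(header):
            raise InconsistentColumnCount(ln, "ragged raw file")
        samples.append(SampleRecord(tok[0], tok[1], tok[2], tok[3], int(tok[4]), tok[5]))
        vals = []
        for k in keep_cols:
            t = tok[k]
            if t in _NA_TOKENS:
                vals.append(np.nan)
            else:
                v = float(t)
                if not (0.0 <= v <= 2.0):
                    raise CountOutOfRange(f"line {ln}: value {t} outside [0, 2]")
                vals.append(v)
        rows.append(vals)
    doses = np.array(rows, dtype=np.float64).T if rows else np.zeros((len(snps), 0))
    payload = DosageMatrix(doses, np.ones(len(snps), dtype=np.int8))
    return Dataset(snps, samples, payload, source_format="recodeA-raw")


# ---------------------------------------------------------------------------
# PHASE / fastPHASE input writers

def write_phase(dataset: Dataset, inp) -> WriteReport:
    """PHASE .inp: sample count, locus count, position line, locus-type
    line, then three lines per individual (id + two allele rows).  Phase is
    unknown here, so heterozygotes list allele1 in the first row."""
    p = _require_hardcalls(dataset)
    first = {MISSING: "?", model.HOM1: None, model.HET: None, model.HOM2: None}
    with open_sink(inp) as fh:
        fh.write(f"{dataset.n_samples}\n{dataset.n_snps}\n")
        fh.write("P " + " ".join(str(s.bp) for s in dataset.snps) + "\n")
        fh.write("S" * dataset.n_snps + "\n")
        for j, s in enumerate(dataset.samples):
            fh.write(f"#{s.iid}\n")
            row1, row2 = [], []
            for i, snp in enumerate(dataset.snps):
                c = int(p.codes[i, j])
                if c == MISSING:
                    row1.append("?")
                    row2.append("?")
                elif c == model.HOM1:
                    row1.append(snp.allele1)
                    row2.append(snp.allele1)
                elif c == model.HET:
                    row1.append(snp.allele1)
                    row2.append(snp.allele2)
                else:
                    row1.append(snp.allele2)
                    row2.append(snp.allele2)
            fh.write(" ".join(row1) + "\n")
            fh.write(" ".join(row2) + "\n")
    rep = WriteReport(files={"inp": sink_name(inp)}, rows={"inp": dataset.n_samples})
    rep.note_loss("pedigree fields beyond the individual id are not representable")
    return rep


def write_fastphase(dataset: Dataset, inp) -> WriteReport:
    """fastPHASE .inp: like PHASE but allele rows are concatenated single
    characters, so multi-character allele labels cannot be written."""
    p = _require_hardcalls(dataset)
    for snp in dataset.snps:
        for a in (snp.allele1, snp.allele2):
            if len(a) != 1:
                raise UnwritableAllele(
                    f"{snp.snp_id}: allele {a!r} is not a single character")
    with open_sink(inp) as fh:
        fh.write(f"{dataset.n_samples}\n{dataset.n_snps}\n")
        fh.write("P " + " ".join(str(s.bp) for s in dataset.snps) + "\n")
        for j, s in enumerate(dataset.samples):
            fh.write(f"# {s.iid}\n")
            row1, row2 = [], []
            for i, snp in enumerate(dataset.snps):
                c = int(p.codes[i, j])
                if c == MISSING:
                    row1.append("?")
                    row2.append("?")
                elif c == model.HOM1:
                    row1.append(snp.allele1)
                    row2.append(snp.allele1)
                elif c == model.HET:
                    row1.append(snp.allele1)
                    row2.append(snp.allele2)
                else:
                    row1.append(snp.allele2)
                    row2.append(snp.allele2)
            fh.write("".join(row1) + "\n")
            fh.write("".join(row2) + "\n")
    rep = WriteReport(files={"inp": sink_name(inp)}, rows={"inp": dataset.n_samples})
    rep.note_loss("pedigree fields beyond the individual id are not representable")
    return rep


# ---------------------------------------------------------------------------
# generic dispatchers

def _need(sources: dict, dialect: FormatDialect) -> None:
    for role in dialect.required_roles:
        if role not in sources:
            raise RoleMissing(f"dialect {dialect.dialect_id!r} requires role {role!r}")


def parse_hardcall(dialect_id: str, sources: dict, options: Optional[dict] = None) -> Dataset:
    """Dispatch to the reader of a hard-call / count dialect.

    ``sources`` maps role names (see DIALECTS) to paths or open streams.
    """
    options = options or {}
    if dialect_id not in DIALECTS:
        raise RoleMissing(f"unknown dialect {dialect_id!r}")
    d = DIALECTS[dialect_id]
    if not d.readable:
        raise UnsupportedPayload(f"dialect {dialect_id!r} is write-only")
    _need(sources, d)
    if dialect_id == "plink-ped":
        return read_ped_map(sources["ped"], sources["map"])
    if dialect_id == "merlin":
        return read_merlin(sources["ped"], sources["dat"], snpinfo=options.get("snpinfo"))
    if dialect_id == "eigensoft":
        return read_eigensoft(sources["geno"], sources["snp"], sources["ind"])
    if dialect_id == "haploview":
        return read_haploview(sources["ped"], sources["info"])
    if dialect_id == "beagle":
        return read_beagle(sources["bgl"])
    if dialect_id == "bimbam":
        return read_bimbam(sources["wbg"], sources.get("pos"))
    if dialect_id == "rgeno":
        return parse_counts(sources, transposed=options.get("transposed", False),
                            snpinfo=options.get("snpinfo"))
    if dialect_id == "recodeA-raw":
        return read_recodeA(sources["raw"])
    raise RoleMissing(f"no reader for dialect {dialect_id!r}")


def parse_counts(sources: dict, transposed: bool = False,
                 snpinfo: Optional[list] = None) -> Dataset:
    """Read an allele-count matrix plus optional snpinfo annotation."""
    if snpinfo is None and "snpinfo" in sources:
        from .manage import read_snpinfo
        snpinfo = read_snpinfo(sources["snpinfo"])
    return read_rgeno(sources["rgeno"], snpinfo=snpinfo, transposed=transposed)


def render_hardcall(dataset: Dataset, dialect_id: str, sinks: dict,
                    options: Optional[dict] = None) -> WriteReport:
    """Dispatch to the writer of a hard-call / count dialect."""
    options = options or {}
    if dialect_id not in DIALECTS:
        raise RoleMissing(f"unknown dialect {dialect_id!r}")
    d = DIALECTS[dialect_id]
    _need(sinks, d)
    if dialect_id == "plink-ped":
        return write_ped_map(dataset, sinks["ped"], sinks["map"])
    if dialect_id == "merlin":
        return write_merlin(dataset, sinks["ped"], sinks["dat"])
    if dialect_id == "eigensoft":
        return write_eigensoft(dataset, sinks["geno"], sinks["snp"], sinks["ind"],
                               group_labels=options.get("group_labels"))
    if dialect_id == "haploview":
        return write_haploview(dataset, sinks["ped"], sinks["info"])
    if dialect_id == "beagle":
        return write_beagle(dataset, sinks["bgl"])
    if dialect_id == "bimbam":
        return write_bimbam(dataset, sinks["wbg"], sinks["pos"])
    if dialect_id == "rgeno":
        return write_r_matrix(dataset, sinks["rgeno"],
                              dose=options.get("dose", False),
                              ref_policy=options.get("ref_policy", "minor"),
                              transpose=options.get("transpose", False))
    if dialect_id == "phase":
        return write_phase(dataset, sinks["inp"])
    if dialect_id == "fastphase":
        return write_fastphase(dataset, sinks["inp"])
    raise RoleMissing(f"no writer for dialect {dialect_id!r}")
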