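"""Dataset algebra: merging, subsetting, chromosome chunking, annotation
updates, hybrid ids, forced field assignment and group labels.

Merging concatenates samples (primary dataset first) and combines SNPs by
intersection (default) or union; allele pairs listed in swapped order in the
two inputs are reconciled by remapping genotype slots, so the underlying
genotypes are preserved.  Chunking splits a bp range into overlapping
windows for chunk-wise imputation, and ``merge_chunk_results`` resolves a
SNP present in an overlap to the chunk where it sits furthest from a chunk
edge (imputation quality degrades near chunk boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import model
from ._io_util import WriteReport, open_sink, open_source, sink_name
from .errors import (
    AlleleMismatch,
    DuplicateSample,
    EmptyResult,
    HeaderMismatch,
    IdCollision,
    JoinKeyAmbiguity,
    PayloadMismatch,
    SampleListMismatch,
)
from .io_pedigree import _fmt_cm
from .model import (
    MISSING,
    Dataset,
    DosageMatrix,
    GenotypeProbabilities,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)


# ---------------------------------------------------------------------------
# merge

def _missing_block(payload_kind: str, n_snps: int, n_samples: int):
    if payload_kind == "hardcalls":
        return np.full((n_snps, n_samples), MISSING, dtype=np.int8)
    if payload_kind == "probabilities":
        return np.zeros((n_snps, n_samples, 3))
    return np.full((n_snps, n_samples), np.nan)


def _payload_rows(payload, idx_or_none, n_samples):
    """One payload row per requested SNP index; None -> missing row."""
    kind = payload.kind
    rows = []
    for idx in idx_or_none:
        if idx is None:
            rows.append(_missing_block(kind, 1, n_samples)[0])
        elif kind == "hardcalls":
            rows.append(payload.codes[idx])
        elif kind == "probabilities":
            rows.append(payload.probs[idx])
        else:
            rows.append(payload.doses[idx])
    return np.array(rows) if rows else _missing_block(kind, 0, n_samples)


def _remap_secondary(payload, i: int, swap: bool):
    """Row i of the secondary payload expressed in the primary's slots."""
    if payload.kind == "hardcalls":
        row = payload.codes[i].copy()
        if swap:
            keep = row != MISSING
            row[keep] = 2 - row[keep]
        return row
    if payload.kind == "probabilities":
        row = payload.probs[i].copy()
        return row[:, ::-1] if swap else row
    row = payload.doses[i].copy()
    return row  # dosage swap handled through ref allele identity by caller


def _allele_orientation(snp_id: str, p1: str, p2: str, s1: str, s2: str) -> bool:
    """Whether the secondary allele pair is slot-swapped w.r.t. the primary.

    "0" (unknown) acts as a wildcard; direct orientation wins when both fit.
    Pairs that cannot be aligned either way raise AlleleMismatch.
    """
    def ok(a, b):
        return a == b or a == "0" or b == "0"

    if ok(s1, p1) and ok(s2, p2):
        return False
    if ok(s1, p2) and ok(s2, p1):
        return True
    raise AlleleMismatch(snp_id, f"{p1}/{p2} vs {s1}/{s2}")


def merge(primary: Dataset, secondary: Dataset, snp_policy: str = "intersect") -> Dataset:
    """Merge two datasets of the same payload kind.

    Samples are concatenated, primary first; a (fid, iid) collision is an
    error.  The SNP set follows ``snp_policy`` ("intersect" or "union");
    with union, genotypes absent from one input are missing.  A SNP whose
    allele pair appears swapped in the secondary input has its genotype
    slots remapped; any other disagreement raises AlleleMismatch.
    """
    if primary.payload.kind != secondary.payload.kind:
        raise PayloadMismatch(
            f"{primary.payload.kind} vs {secondary.payload.kind}")
    if snp_policy not in ("intersect", "union"):
        raise ValueError(f"unknown snp_policy {snp_policy!r}")

    keys = {s.key for s in primary.samples}
    for s in secondary.samples:
        if s.key in keys:
            raise DuplicateSample(f"{s.fid} {s.iid} present in both inputs")

    sec_index = secondary.snp_index()
    if snp_policy == "intersect":
        out_snps = [s for s in primary.snps if s.snp_id in sec_index]
    else:
        out_snps = list(primary.snps)
        prim_ids = {s.snp_id for s in primary.snps}
        out_snps += [s for s in secondary.snps if s.snp_id not in prim_ids]
    if not out_snps:
        raise EmptyResult("merge produced no SNPs")

    prim_index = primary.snp_index()
    n1, n2 = primary.n_samples, secondary.n_samples
    kind = primary.payload.kind
    prim_rows, sec_rows, merged_snps = [], [], []
    for snp in out_snps:
        pi = prim_index.get(snp.snp_id)
        si = sec_index.get(snp.snp_id)
        rec = (primary.snps[pi] if pi is not None else secondary.snps[si]).copy()

        if pi is None:
            prim_rows.append(_missing_block(kind, 1, n1)[0])
        else:
            prim_rows.append(_payload_rows(primary.payload, [pi], n1)[0])

        if si is None:
            sec_rows.append(_missing_block(kind, 1, n2)[0])
        elif pi is None:
            sec_rows.append(_remap_secondary(secondary.payload, si, swap=False))
        else:
            p1, p2 = primary.snps[pi].allele1, primary.snps[pi].allele2
            s1, s2 = secondary.snps[si].allele1, secondary.snps[si].allele2
            swap = _allele_orientation(snp.snp_id, p1, p2, s1, s2)
            sec_rows.append(_remap_secondary(secondary.payload, si, swap=swap))
            # fill unknown slots of the merged record from the secondary
            fill1, fill2 = (s2, s1) if swap else (s1, s2)
            if rec.allele1 == "0" and fill1 != "0":
                rec.allele1 = fill1
            if rec.allele2 == "0" and fill2 != "0":
                rec.allele2 = fill2
        merged_snps.append(rec)

    prim_block = np.array(prim_rows)
    sec_block = np.array(sec_rows)
    if kind == "hardcalls":
        payload = HardCallMatrix(np.concatenate(
            [prim_block.astype(np.int8), sec_block.astype(np.int8)], axis=1))
    elif kind == "probabilities":
        payload = GenotypeProbabilities(np.concatenate([prim_block, sec_block], axis=1))
    else:
        # dosage merge keeps the primary's reference slots; the secondary's
        # doses are re-expressed against them via the allele identity
        ref = []
        for snp in merged_snps:
            pi = prim_index.get(snp.snp_id)
            if pi is not None:
                ref.append(primary.payload.ref_slot[pi])
            else:
                ref.append(secondary.payload.ref_slot[sec_index[snp.snp_id]])
        ref = np.array(ref, dtype=np.int8)
        for k, snp in enumerate(merged_snps):
            pi = prim_index.get(snp.snp_id)
            si = sec_index.get(snp.snp_id)
            if pi is None or si is None:
                continue
            prim_ref_allele = (primary.snps[pi].allele1 if ref[k] == 1
                               else primary.snps[pi].allele2)
            sec = secondary.snps[si]
            sec_ref_allele = sec.allele1 if secondary.payload.ref_slot[si] == 1 else sec.allele2
            if sec_ref_allele != prim_ref_allele and "0" not in (sec_ref_allele, prim_ref_allele):
                sec_block[k] = 2.0 - sec_block[k]
        payload = DosageMatrix(np.concatenate([prim_block, sec_block], axis=1), ref)

    return Dataset(merged_snps, [s.copy() for s in primary.samples]
                   + [s.copy() for s in secondary.samples],
                   payload, source_format=primary.source_format)


# ---------------------------------------------------------------------------
# subset

def subset(dataset: Dataset, keep_snps=None, remove_snps=None,
           keep_samples=None, remove_samples=None) -> Dataset:
    """Row/column subset by id lists; order is preserved.

    Sample ids may be (fid, iid) tuples or bare iids.  Unknown ids produce
    a warning, not an error; an empty result is an error.
    """
    if keep_snps is not None and remove_snps is not None:
        raise ValueError("give at most one of keep_snps/remove_snps")
    if keep_samples is not None and remove_samples is not None:
        raise ValueError("give at most one of keep_samples/remove_samples")

    snp_ids = [s.snp_id for s in dataset.snps]

    def _mask(universe, keys, keep, listed):
        known = set(universe)
        unknown = [k for k in listed if k not in known]
        if unknown:
            warnings.warn(f"unknown ids ignored: {unknown[:5]}"
                          + ("..." if len(unknown) > 5 else ""))
        sel = set(listed)
        return np.array([(k in sel) == keep for k in keys], dtype=bool)

    keep_snp = np.ones(dataset.n_snps, dtype=bool)
    if keep_snps is not None:
        keep_snp = _mask(snp_ids, snp_ids, True, list(keep_snps))
    elif remove_snps is not None:
        keep_snp = _mask(snp_ids, snp_ids, False, list(remove_snps))

    def _sample_key(x):
        return x if isinstance(x, tuple) else None

    keep_samp = np.ones(dataset.n_samples, dtype=bool)
    if keep_samples is not None or remove_samples is not None:
        listed = list(keep_samples if keep_samples is not None else remove_samples)
        keep = keep_samples is not None
        if listed and isinstance(listed[0], tuple):
            keys = [s.key for s in dataset.samples]
        else:
            keys = [s.iid for s in dataset.samples]
        keep_samp = _mask(keys, keys, keep, listed)

    if not keep_snp.any():
        raise EmptyResult("subset removes every SNP")
    if not keep_samp.any():
        raise EmptyResult("subset removes every sample")
    from .qc import _take
    return _take(dataset, keep_snp, keep_samp)


# ---------------------------------------------------------------------------
# chunking

@dataclass
class ChunkSpec:
    """Overlapping bp windows over one chromosome region."""

    chrom: str
    range_start: int
    range_end: int
    chunk_len: int
    overlap: int

    def __post_init__(self):
        if not 0 < self.overlap < self.chunk_len:
            raise ValueError("require 0 < overlap < chunk_len")
        if self.range_start > self.range_end:
            raise ValueError("range_start must be <= range_end")


def make_chunks(spec: ChunkSpec) -> list:
    """Inclusive (lower, upper) bounds covering the range with the requested
    overlap; only the final chunk may be shorter."""
    step = spec.chunk_len - spec.overlap
    bounds = []
    i = 0
    while True:
        lo = spec.range_start + i * step
        hi = lo + spec.chunk_len - 1
        if hi >= spec.range_end:
            bounds.append((lo, spec.range_end))
            break
        bounds.append((lo, hi))
        i += 1
    return bounds


def merge_chunk_results(chunks: list, bounds: list) -> Dataset:
    """Combine chunk-wise datasets back into one.

    All chunks must share the sample list.  A SNP appearing in several
    chunks (the overlaps) is taken from the chunk where its distance to the
    nearer chunk edge is maximal; ties go to the earlier chunk.  Output
    keeps first-appearance SNP order.
    """
    if not chunks:
        raise EmptyResult("no chunks to merge")
    ref_keys = [s.key for s in chunks[0].samples]
    for ds in chunks[1:]:
        if [s.key for s in ds.samples] != ref_keys:
            raise SampleListMismatch("chunks disagree on the sample list")
    kind = chunks[0].payload.kind
    for ds in chunks[1:]:
        if ds.payload.kind != kind:
            raise PayloadMismatch("chunks carry different payload kinds")

    best = {}   # snp_id -> (edge_dist, chunk_idx, snp_idx)
    order = []
    for k, (ds, (lo, hi)) in enumerate(zip(chunks, bounds)):
        for i, snp in enumerate(ds.snps):
            d = min(snp.bp - lo, hi - snp.bp)
            cur = best.get(snp.snp_id)
            if cur is None:
                order.append(snp.snp_id)
                best[snp.snp_id] = (d, k, i)
            elif d > cur[0]:  # strict: ties keep the earlier chunk
                best[snp.snp_id] = (d, k, i)

    snps, rows, ref = [], [], []
    for sid in order:
        _, k, i = best[sid]
        ds = chunks[k]
        snps.append(ds.snps[i].copy())
        if kind == "hardcalls":
            rows.append(ds.payload.codes[i])
        elif kind == "probabilities":
            rows.append(ds.payload.probs[i])
        else:
            rows.append(ds.payload.doses[i])
            ref.append(ds.payload.ref_slot[i])
    block = np.array(rows)
    if kind == "hardcalls":
        payload = HardCallMatrix(block.astype(np.int8))
    elif kind == "probabilities":
        payload = GenotypeProbabilities(block)
    else:
        payload = DosageMatrix(block, np.array(ref, dtype=np.int8))
    return Dataset(snps, [s.copy() for s in chunks[0].samples], payload,
                   source_format=chunks[0].source_format)


# ---------------------------------------------------------------------------
# annotation updates

_EMPTY_TOKENS = {"", "."}


def update_info(dataset: Dataset, snpinfo: Optional[list] = None,
                pedinfo: Optional[list] = None,
                pedinfo_by_position: bool = False) -> Dataset:
    """Fill or overwrite SNP / pedigree annotation from side tables.

    snpinfo joins on snp_id; pedinfo on (fid, iid), or by row position when
    ``pedinfo_by_position`` is set (useful for formats that carry no real
    ids).  Non-empty incoming fields overwrite; empty fields ("" or ".",
    unknown codes "0"/0) leave existing values.  Allele labels are filled
    only into unknown ("0") slots -- relabelling known alleles would detach
    the labels from the stored genotype slots.
    """
    ds = dataset.copy()
    if snpinfo is not None:
        by_id = {}
        for rec in snpinfo:
            if rec.snp_id in by_id:
                raise JoinKeyAmbiguity(f"snpinfo lists {rec.snp_id} twice")
            by_id[rec.snp_id] = rec
        for snp in ds.snps:
            rec = by_id.get(snp.snp_id)
            if rec is None:
                continue
            if rec.chrom not in {"0"} | _EMPTY_TOKENS:
                snp.chrom = rec.chrom
            if rec.cm:
                snp.cm = rec.cm
            if rec.bp:
                snp.bp = rec.bp
            if snp.allele1 == "0" and rec.allele1 != "0":
                snp.allele1 = rec.allele1
            if snp.allele2 == "0" and rec.allele2 != "0":
                snp.allele2 = rec.allele2
    if pedinfo is not None:
        if pedinfo_by_position:
            for sample, rec in zip(ds.samples, pedinfo):
                _update_sample(sample, rec, overwrite_ids=True)
            if len(pedinfo) != ds.n_samples:
                warnings.warn("pedinfo row count differs from sample count")
        else:
            by_key = {}
            for rec in pedinfo:
                if rec.key in by_key:
                    raise JoinKeyAmbiguity(f"pedinfo lists {rec.fid} {rec.iid} twice")
                by_key[rec.key] = rec
            matched = set()
            for sample in ds.samples:
                rec = by_key.get(sample.key)
                if rec is not None:
                    _update_sample(sample, rec)
                    matched.add(rec.key)
            unmatched = set(by_key) - matched
            if unmatched:
                warnings.warn(f"pedinfo rows for absent samples skipped: "
                              f"{sorted(unmatched)[:5]}")
    return ds


def _update_sample(sample: SampleRecord, rec: SampleRecord,
                   overwrite_ids: bool = False) -> None:
    if overwrite_ids:
        if rec.fid not in _EMPTY_TOKENS:
            sample.fid = rec.fid
        if rec.iid not in _EMPTY_TOKENS:
            sample.iid = rec.iid
    if rec.pat not in {"0"} | _EMPTY_TOKENS:
        sample.pat = rec.pat
    if rec.mat not in {"0"} | _EMPTY_TOKENS:
        sample.mat = rec.mat
    if rec.sex:
        sample.sex = rec.sex
    if rec.phenotype not in _EMPTY_TOKENS:
        sample.phenotype = rec.phenotype


# ---------------------------------------------------------------------------
# info/list tables

def read_snpinfo(source) -> list:
    """Tab/space table with header snp_id chrom cm bp allele1 allele2."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows or rows[0][0] != "snp_id":
        raise HeaderMismatch("snpinfo file must start with a 'snp_id ...' header")
    idx = {h: k for k, h in enumerate(rows[0])}
    out = []
    for tok in rows[1:]:
        out.append(SnpRecord(
            chrom=tok[idx["chrom"]] if "chrom" in idx else "0",
            snp_id=tok[idx["snp_id"]],
            cm=float(tok[idx["cm"]]) if "cm" in idx else 0.0,
            bp=int(tok[idx["bp"]]) if "bp" in idx else 0,
            allele1=tok[idx["allele1"]] if "allele1" in idx else "0",
            allele2=tok[idx["allele2"]] if "allele2" in idx else "0",
        ))
    return out


def read_pedinfo(source) -> list:
    """Tab/space table with header fid iid pat mat sex phenotype."""
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows or rows[0][:2] != ["fid", "iid"]:
        raise HeaderMismatch("pedinfo file must start with a 'fid iid ...' header")
    idx = {h: k for k, h in enumerate(rows[0])}
    out = []
    for tok in rows[1:]:
        out.append(SampleRecord(
            fid=tok[idx["fid"]],
            iid=tok[idx["iid"]],
            pat=tok[idx["pat"]] if "pat" in idx else "0",
            mat=tok[idx["mat"]] if "mat" in idx else "0",
            sex=int(tok[idx["sex"]]) if "sex" in idx else 0,
            phenotype=tok[idx["phenotype"]] if "phenotype" in idx else model.MISSING_PHENO,
        ))
    return out


def write_lists(dataset: Dataset, which: str, sink) -> WriteReport:
    """Write snplist / pedlist / snpinfo / pedinfo files.

    snplist is one snp_id per line and pedlist one "fid iid" per line; the
    *info variants are full annotation tables that :func:`update_info` can
    re-import.
    """
    with open_sink(sink) as fh:
        if which == "snplist":
            for s in dataset.snps:
                fh.write(s.snp_id + "\n")
            n = dataset.n_snps
        elif which == "pedlist":
            for s in dataset.samples:
                fh.write(f"{s.fid} {s.iid}\n")
            n = dataset.n_samples
        elif which == "snpinfo":
            fh.write("snp_id chrom cm bp allele1 allele2\n")
            for s in dataset.snps:
                fh.write(f"{s.snp_id} {s.chrom} {_fmt_cm(s.cm)} {s.bp} "
                         f"{s.allele1} {s.allele2}\n")
            n = dataset.n_snps
        elif which == "pedinfo":
            fh.write("fid iid pat mat sex phenotype\n")
            for s in dataset.samples:
                fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} {s.phenotype}\n")
            n = dataset.n_samples
        else:
            raise ValueError(f"unknown list kind {which!r}")
    return WriteReport(files={which: sink_name(sink)}, rows={which: n})


# ---------------------------------------------------------------------------
# ids, forcing, group labels

def hybrid_ids(samples: list, fields: list, separator: str = "_") -> list:
    """Join pedigree fields into one id per sample; collisions are errors."""
    if not fields:
        raise ValueError("pattern must name at least one field")
    for f in fields:
        if f not in ("fid", "iid", "pat", "mat"):
            raise ValueError(f"unknown id field {f!r}")
    ids, seen = [], {}
    for s in samples:
        hid = separator.join(getattr(s, f) for f in fields)
        if hid in seen:
            raise IdCollision(f"hybrid id {hid!r} produced by two samples")
        seen[hid] = s
        ids.append(hid)
    return ids


@dataclass
class ForceDirective:
    """Forced assignment: phenotype (aff/unaff), sex (male/female) or the
    reference allele (minor/major/first/second) of every SNP."""

    target: str
    value: str

    _LEGAL = {
        "pheno": {"aff", "unaff"},
        "sex": {"male", "female"},
        "ref-allele": {"minor", "major", "first", "second"},
    }

    def __post_init__(self):
        if self.target not in self._LEGAL:
            raise ValueError(f"unknown force target {self.target!r}")
        if self.value not in self._LEGAL[self.target]:
            raise ValueError(f"illegal value {self.value!r} for {self.target}")


def force_assign(dataset: Dataset, directive: ForceDirective) -> Dataset:
    """Apply a ForceDirective to every sample (pheno/sex) or SNP (ref-allele).

    Case/control coding follows PLINK: affected = "2", unaffected = "1".
    Forcing the reference allele re-expresses a dosage payload against the
    newly resolved allele; for other payloads the policy takes effect when
    a count/dose output is rendered.
    """
    ds = dataset.copy()
    if directive.target == "pheno":
        v = "2" if directive.value == "aff" else "1"
        for s in ds.samples:
            s.phenotype = v
    elif directive.target == "sex":
        v = 1 if directive.value == "male" else 2
        for s in ds.samples:
            s.sex = v
    else:
        if isinstance(ds.payload, DosageMatrix):
            new_slots = model._resolve_ref_slots(ds, directive.value)
            flip = new_slots != ds.payload.ref_slot
            ds.payload.doses[flip] = 2.0 - ds.payload.doses[flip]
            ds.payload.ref_slot = new_slots
        # hard-call / probability payloads are slot-anchored; the reference
        # policy applies when counts or doses are rendered
    return ds


def attach_group_labels(samples: list, labels, default: str = "Unknown") -> dict:
    """Resolve a 2-column (sample id, label) table against the sample list.

    Ids match iid first, then "fid_iid" hybrids.  Unresolvable ids warn;
    duplicate rows for one sample keep the last label (with a warning).
    Returns iid -> label for every sample, ``default`` where unlabeled.
    """
    if not isinstance(labels, dict):
        pairs = list(labels)
    else:
        pairs = list(labels.items())
    by_iid = {s.iid: s for s in samples}
    by_hybrid = {f"{s.fid}_{s.iid}": s for s in samples}
    out = {s.iid: default for s in samples}
    assigned = set()
    for token, label in pairs:
        s = by_iid.get(token) or by_hybrid.get(token)
        if s is None:
            warnings.warn(f"group label for unresolvable id {token!r} ignored")
            continue
        if s.iid in assigned:
            warnings.warn(f"duplicate group label rows for {s.iid!r}; last wins")
        out[s.iid] = label
        assigned.add(s.iid)
    return out


def read_group_labels(source) -> list:
    with open_source(source) as fh:
        rows = [line.split() for line in fh if line.strip()]
    out = []
    for ln, tok in enumerate(rows, 1):
        if len(tok) < 2:
            raise HeaderMismatch(f"group-label line {ln} needs id and label")
        out.append((tok[0], tok[1]))
    return out
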