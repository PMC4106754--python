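"""Bit-exact codec for PLINK binary bed/bim/fam triples.

The .bed payload packs four genotypes per byte, least-significant bit pair
first, in SNP-major order (mode byte 0x01): 00 = hom A1, 10 = het,
11 = hom A2, 01 = missing.  Pad bits of a trailing partial byte are zero.
bim/fam are whitespace text and accept ``.gz``; the bed stream itself is
always raw binary.
"""

from __future__ import annotations

import numpy as np

from ._io_util import WriteReport, open_sink, open_source, sink_name
from .errors import (
    BadMagic,
    InconsistentColumnCount,
    LengthMismatch,
    UnsupportedMode,
    UnsupportedPayload,
)
from .model import (
    HET,
    HOM1,
    HOM2,
    MISSING,
    Dataset,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)

MAGIC = b"\x6c\x1b"
SNP_MAJOR = 0x01

# 2-bit value -> genotype code (count of allele2)
_BITS_TO_CODE = np.array([HOM1, MISSING, HET, HOM2], dtype=np.int8)
_CODE_TO_BITS = {HOM1: 0, MISSING: 1, HET: 2, HOM2: 3}


def decode_bed_byte(b: int, n_remaining: int) -> list:
    """Unpack one bed byte into up to four genotype codes.

    Genotypes come from the least-significant bit pair upward; only the
    first ``n_remaining`` (1..4) pairs of the final byte of a SNP block
    carry data.
    """
    if not 1 <= n_remaining <= 4:
        raise ValueError("n_remaining must be in [1, 4]")
    return [int(_BITS_TO_CODE[(b >> (2 * k)) & 0b11]) for k in range(n_remaining)]


def encode_bed_byte(codes) -> int:
    """Inverse of :func:`decode_bed_byte`; unused slots pack as 00."""
    b = 0
    for k, c in enumerate(codes):
        b |= _CODE_TO_BITS[int(c)] << (2 * k)
    return b


def read_bim(source) -> list:
    snps = []
    with open_source(source) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6:
                raise InconsistentColumnCount(ln, f"bim line has {len(tok)} columns")
            chrom, sid, cm, bp, a1, a2 = tok
            snps.append(SnpRecord(chrom, sid, float(cm), int(bp), a1, a2))
    return snps


def read_fam(source) -> list:
    samples = []
    with open_source(source) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6:
                raise InconsistentColumnCount(ln, f"fam line has {len(tok)} columns")
            samples.append(SampleRecord(tok[0], tok[1], tok[2], tok[3], int(tok[4]), tok[5]))
    return samples


def read_bed(bed, bim, fam) -> Dataset:
    """Decode a bed/bim/fam triple into a hard-call dataset.

    A1 maps to allele1 and A2 to allele2 verbatim; no minor/major
    re-inference happens at read time.  Individual-major files (mode 0x00)
    are rejected rather than silently transposed.
    """
    snps = read_bim(bim)
    samples = read_fam(fam)
    n_snps, n_samples = len(snps), len(samples)
    bpb = (n_samples + 3) // 4  # bytes per SNP block

    with open_source(bed, binary=True) as fh:
        data = fh.read()
    if len(data) < 3 or data[:2] != MAGIC:
        raise BadMagic("not a PLINK bed file (magic bytes 6c 1b absent)")
    if data[2] != SNP_MAJOR:
        raise UnsupportedMode(
            f"bed mode byte 0x{data[2]:02x}; only SNP-major (0x01) is supported")
    if len(data) != 3 + bpb * n_snps:
        raise LengthMismatch(
            f"bed payload is {len(data) - 3} bytes, expected {bpb * n_snps} "
            f"({n_snps} SNPs x {bpb} bytes)")

    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(n_snps, bpb)
    # expand each byte into its four 2-bit fields, low pair first
    shifts = np.arange(4, dtype=np.uint8) * 2
    bits = (raw[:, :, None] >> shifts) & 0b11
    codes = _BITS_TO_CODE[bits.reshape(n_snps, bpb * 4)[:, :n_samples]]
    return Dataset(snps, samples, HardCallMatrix(codes), source_format="plink-bed")


def write_bed(dataset: Dataset, bed, bim, fam) -> WriteReport:
    """Encode a hard-call dataset as bed/bim/fam (SNP-major, zero padding)."""
    if not isinstance(dataset.payload, HardCallMatrix):
        raise UnsupportedPayload("PLINK binary requires a hard-call payload")
    codes = dataset.payload.codes
    n_snps, n_samples = codes.shape
    bpb = (n_samples + 3) // 4

    bits = np.empty((n_snps, bpb * 4), dtype=np.uint8)
    bits[:] = 0  # pad slots encode as 00
    lut = np.zeros(256, dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        lut[code & 0xFF] = b  # int8 -1 (missing) indexes as 255
    bits[:, :n_samples] = lut[codes.view(np.uint8)]
    bits = bits.reshape(n_snps, bpb, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (bits << shifts).sum(axis=2).astype(np.uint8)

    with open_sink(bed, binary=True) as fh:
        fh.write(MAGIC + bytes([SNP_MAJOR]))
        fh.write(packed.tobytes())
    from .io_pedigree import _fmt_cm
    with open_sink(bim) as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t{_fmt_cm(s.cm)}\t{s.bp}\t{s.allele1}\t{s.allele2}\n")
    with open_sink(fam) as fh:
        for s in dataset.samples:
            fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} {s.phenotype}\n")
    return WriteReport(
        files={"bed": sink_name(bed), "bim": sink_name(bim), "fam": sink_name(fam)},
        rows={"bed": n_snps, "bim": n_snps, "fam": n_samples},
    )
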