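"""Exception hierarchy for genoconv.

Every error raised by readers, writers, transforms and dataset algebra is a
subclass of :class:`GenoconvError`, so callers (notably the CLI) can catch
one type and still report a precise reason.
"""


class GenoconvError(Exception):
    """Base class for all genoconv errors."""


# --- parsing -------------------------------------------------------------

class MalformedLine(GenoconvError):
    def __init__(self, line_no: int, reason: str):
        self.line_no = line_no
        self.reason = reason
        super().__init__(f"line {line_no}: {reason}")


class RoleMissing(GenoconvError):
    """A file role required by the dialect was not supplied."""


class InconsistentColumnCount(MalformedLine):
    pass


class UnknownAlleleToken(GenoconvError):
    pass


class HeaderMismatch(GenoconvError):
    pass


class CountOutOfRange(GenoconvError):
    pass


# --- PLINK binary --------------------------------------------------------

class BadMagic(GenoconvError):
    pass


class UnsupportedMode(GenoconvError):
    pass


class LengthMismatch(GenoconvError):
    pass


# --- imputation formats --------------------------------------------------

class OrientationMismatch(GenoconvError):
    pass


class BadIdToken(GenoconvError):
    pass


class TripletCountMismatch(GenoconvError):
    pass


class MissingAlleleLabels(GenoconvError):
    pass


class KindUndeclared(GenoconvError):
    pass


class SampleMismatch(GenoconvError):
    pass


class MissingPosition(GenoconvError):
    pass


# --- payload conversion / writing ---------------------------------------

class UnsupportedConversion(GenoconvError):
    pass


class UnsupportedPayload(GenoconvError):
    pass


class UnwritableAllele(GenoconvError):
    pass


# --- QC ------------------------------------------------------------------

class QualityTableMissing(GenoconvError):
    pass


# --- transforms ----------------------------------------------------------

class MonomorphicAmbiguity(GenoconvError):
    pass


class UnknownSnpId(GenoconvError):
    pass


class NonNucleotideAllele(GenoconvError):
    pass


# --- dataset algebra -----------------------------------------------------

class DuplicateSample(GenoconvError):
    pass


class AlleleMismatch(GenoconvError):
    def __init__(self, snp_id: str, detail: str = ""):
        self.snp_id = snp_id
        super().__init__(f"irreconcilable alleles at {snp_id}" + (f": {detail}" if detail else ""))


class PayloadMismatch(GenoconvError):
    pass


class EmptyResult(GenoconvError):
    pass


class SampleListMismatch(GenoconvError):
    pass


class JoinKeyAmbiguity(GenoconvError):
    pass


class IdCollision(GenoconvError):
    pass


# --- CLI ------------------------------------------------------------------

class UnknownFlag(GenoconvError):
    pass


class UnbalancedBlock(GenoconvError):
    pass


class ConflictingInputs(GenoconvError):
    pass
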