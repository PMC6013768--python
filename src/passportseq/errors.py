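"""Exception hierarchy shared across the toolkit.

Every error raised by the library derives from :class:`PassportSeqError`,
so callers (and the CLI) can catch one base class. Errors that carry the
identity of the offending record expose it as an attribute.
"""


class PassportSeqError(Exception):
    """Base class for all passportseq errors."""


# ---------------------------------------------------------------- design
class DesignError(PassportSeqError):
    """Base class for panel-design errors."""


class InsufficientFlank(DesignError):
    """Flanking sequence too short to build the requested window."""


class NonSNV(DesignError):
    """Variant is not a single-nucleotide substitution."""


class InvalidBase(DesignError):
    """Sequence contains a character outside {A, C, G, T}."""


class InvalidWindow(DesignError):
    """Test window has the wrong length or alphabet."""


class DuplicateWindow(DesignError):
    """Two panel entries produced identical fragment bodies."""

    def __init__(self, message, snp_ids=()):
        super().__init__(message)
        self.snp_ids = tuple(snp_ids)


# ------------------------------------------------------------- seed scan
class MiRNATooShort(PassportSeqError):
    """miRNA sequence shorter than the 8 nt needed for a seed."""


# -------------------------------------------------------------- readproc
class DuplicateBarcodePair(PassportSeqError):
    """Two sample-sheet rows share the same (fwd, rev) barcode pair."""


class UnknownFragmentId(PassportSeqError):
    """Assignment references a fragment absent from the library."""


class NoInputSamples(PassportSeqError):
    """Operation requires input-plasmid samples but none are present."""


class TooFewReplicates(PassportSeqError):
    """Fewer replicates than the operation needs."""


# ---------------------------------------------------------------- diffex
class MissingFactor(PassportSeqError):
    """No input-correction factor available for a SNP."""


class DegenerateData(PassportSeqError):
    """Count data carry no information (e.g. all zeros)."""


class NonConvergence(PassportSeqError):
    """IRLS failed to converge within the iteration budget."""


class PanelMismatch(PassportSeqError):
    """Two runs do not cover the same SNP panel."""

    def __init__(self, message, snp_ids=()):
        super().__init__(message)
        self.snp_ids = tuple(snp_ids)


# -------------------------------------------------------------- simulate
class ConfigError(PassportSeqError):
    """Simulation or pipeline configuration is invalid."""


class TooManySamples(PassportSeqError):
    """Barcode space cannot accommodate the requested sample count."""


# -------------------------------------------------------------------- io
class SchemaError(PassportSeqError):
    """Tabular input violates its documented schema."""


class ParseError(PassportSeqError):
    """File could not be parsed at all."""
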