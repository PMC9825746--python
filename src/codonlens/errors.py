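"""Exception hierarchy for the codonlens pipeline."""


class CodonlensError(Exception):
    """Base class for all codonlens errors."""


class InvalidCodonError(CodonlensError, ValueError):
    """A codon string is not three unambiguous DNA bases."""


class InvalidSequenceError(CodonlensError, ValueError):
    """A nucleotide sequence is empty or contains non-IUPAC characters."""


class InvalidCodeError(CodonlensError, ValueError):
    """A genetic-code table violates its invariants."""


class ProfileFormatError(CodonlensError, ValueError):
    """A profile HMM file cannot be parsed; the message names the record."""


class InvalidDistributionError(CodonlensError, ValueError):
    """A probability distribution does not sum to one or has negative mass."""


class NoConsensusColumnsError(CodonlensError, ValueError):
    """An alignment has no columns with <=50% gaps to build match states from."""


class MissingExecutableError(CodonlensError, RuntimeError):
    """An external search tool is not on PATH; use the internal aligner."""


class SearchFailedError(CodonlensError, RuntimeError):
    """The external search exited non-zero; diagnostics attached."""


class TruncatedAlignmentError(CodonlensError, ValueError):
    """An alignment block ended before its declared coordinates were reached."""


class CoordinateError(CodonlensError, ValueError):
    """A residue position maps outside its source sequence."""


class UnknownProfileError(CodonlensError, KeyError):
    """A segment references a profile with no loaded emissions."""


class EncodingError(CodonlensError, ValueError):
    """A protein residue has no codon under the requested genetic code."""
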