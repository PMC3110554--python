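"""Exception hierarchy for hpulse.

All recoverable failures raise a subclass of :class:`HPulseError`, so callers
(and the CLI) can catch one type and print a clean message.
"""


class HPulseError(Exception):
    """Base class for all hpulse errors."""


class SequenceError(HPulseError):
    """Invalid residue, position out of range, or sequence too short."""


class AnnotationError(HPulseError):
    """Inconsistent per-residue annotation (gaps, residue mismatch, ...)."""


class FormatError(HPulseError):
    """Malformed input file (FASTA, STRIDE, PDBTM XML, TSV)."""
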