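"""Kyte-Doolittle hydropathy scale.

The scale assigns each of the 20 canonical amino acids a dimensionless
hydropathy value; isoleucine is the most hydrophobic (+4.5) and arginine the
least (-4.5).  Every hydrophobicity-variation score in this package is
computed from these values, so the scale lives in one place and is treated
as immutable.
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Mapping

from .errors import SequenceError

#: Kyte-Doolittle hydropathy values, one-letter residue code -> KD units.
KD_SCALE: Mapping[str, float] = MappingProxyType(
    {
        "I": 4.5,
        "V": 4.2,
        "L": 3.8,
        "F": 2.8,
        "C": 2.5,
        "M": 1.9,
        "A": 1.8,
        "G": -0.4,
        "T": -0.7,
        "S": -0.8,
        "W": -0.9,
        "Y": -1.3,
        "P": -1.6,
        "H": -3.2,
        "E": -3.5,
        "Q": -3.5,
        "D": -3.5,
        "N": -3.5,
        "K": -3.9,
        "R": -4.5,
    }
)

CANONICAL_RESIDUES = frozenset(KD_SCALE)


def kd_value(residue: str, position: int | None = None) -> float:
    """Return the Kyte-Doolittle hydropathy of a one-letter residue code.

    Parameters
    ----------
    residue
        Upper-case one-letter amino-acid code.
    position
        Optional 1-based sequence position, used only to improve the error
        message for non-canonical codes.

    Raises
    ------
    SequenceError
        For non-canonical codes (B, J, O, U, X, Z, ...).  Ambiguity codes are
        rejected rather than imputed: no hydropathy is defined for them and a
        silent guess would shift pulse positions.
    """
    try:
        return KD_SCALE[residue]
    except KeyError:
        where = f" at position {position}" if position is not None else ""
        raise SequenceError(
            f"non-canonical residue {residue!r}{where}: no Kyte-Doolittle "
            "value is defined for it"
        ) from None


def validate_sequence(seq: str) -> str:
    """Upper-case *seq* and reject any non-canonical residue."""
    seq = seq.upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in CANONICAL_RESIDUES:
            kd_value(aa, pos)  # raises with position info
    return seq
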