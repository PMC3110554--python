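"""Sinus-weighted hydrophobicity-variation scoring.

For a residue at position ``i`` and a window radius ``n`` the score is the
difference between the sinus-weighted hydropathy of the ``n`` residues that
follow ``i`` and the identically weighted hydropathy of the ``n`` residues
that precede it:

    score(i, n) = sum_{k=1..n} sin(k*pi/(n+1)) * [KD(i+k) - KD(i-k)]

The half-sine weight peaks mid-window and vanishes at the window edge, so a
rise of hydrophobicity a few residues downstream of ``i`` pulls the score
positive while the residues farthest from ``i`` contribute least.  The window
spans 2n+1 residues; the central residue carries no weight (it appears in
neither sum), which makes the score exactly antisymmetric under sequence
reversal.

Two window-radius groups are analysed: G1 (n = 2..6) resolves small
structural events on the scale of single helix turns, while G2 (n = 12..16)
resolves transmembrane-helix-sized events (a membrane-spanning helix is about
21 residues, i.e. n ~ 10).  Intermediate radii carry no extra information and
are not computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Literal

import numpy as np

from .errors import SequenceError
from .scale import KD_SCALE, validate_sequence

Group = Literal["G1", "G2"]

#: Window radii per group: G1 for small events, G2 for TMH-scale events.
GROUP_RADII: dict[str, tuple[int, ...]] = {
    "G1": (2, 3, 4, 5, 6),
    "G2": (12, 13, 14, 15, 16),
}


@lru_cache(maxsize=None)
def sinus_weights(n: int) -> np.ndarray:
    """Half-sine weights ``sin(k*pi/(n+1))`` for offsets ``k = 1..n``."""
    if n < 1:
        raise ValueError(f"window radius must be >= 1, got {n}")
    k = np.arange(1, n + 1)
    return np.sin(k * np.pi / (n + 1))


def _kd_array(seq: str) -> np.ndarray:
    seq = validate_sequence(seq)
    return np.array([KD_SCALE[aa] for aa in seq], dtype=float)


def variation_score(seq: str, i: int, n: int) -> float:
    """Hydrophobicity-variation score at 1-based position *i*, radius *n*.

    Requires ``n+1 <= i <= L-n`` so that all 2n+1 window residues exist;
    positions outside that range are undefined and raise ``SequenceError``
    rather than being padded or zero-filled.
    """
    kd = _kd_array(seq)
    L = len(kd)
    if not (n + 1 <= i <= L - n):
        raise SequenceError(
            f"position {i} undefined for radius {n}: the window needs "
            f"positions {i - n}..{i + n} but the sequence has length {L} "
            f"(defined range is [{n + 1}, {L - n}])"
        )
    w = sinus_weights(n)
    j = i - 1  # 0-based centre
    following = kd[j + 1 : j + 1 + n]
    preceding = kd[j - n : j][::-1]  # preceding[k-1] = KD(i-k)
    return float(w @ following - w @ preceding)


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-position variation scores for the five radii of one group.

    ``scores`` has shape ``(5, L)``; column ``i-1`` holds the scores of
    1-based position ``i``.  Positions where a radius's window does not fit
    are NaN — an explicit "undefined" marker, never a silent zero.
    """

    sequence_id: str
    group: Group
    radii: tuple[int, ...]
    scores: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    def defined_range(self, n: int) -> tuple[int, int] | None:
        """Inclusive 1-based range where radius *n* is defined, or None."""
        if n not in self.radii:
            raise KeyError(f"radius {n} not in group {self.group}")
        lo, hi = n + 1, self.length - n
        return (lo, hi) if lo <= hi else None

    @property
    def common_range(self) -> tuple[int, int]:
        """Range where all five radii are defined: [max(n)+1, L-max(n)]."""
        n = max(self.radii)
        return n + 1, self.length - n

    def track(self, n: int) -> np.ndarray:
        """Score track for one radius (length-L array, NaN = undefined)."""
        return self.scores[self.radii.index(n)]

    def iter_positions(self) -> Iterator[int]:
        lo, hi = self.common_range
        return iter(range(lo, hi + 1))


def min_length(group: Group) -> int:
    """Shortest sequence for which the group has >= 1 defined score:
    2*min(radii) + 1 (the smallest radius's window must fit somewhere)."""
    return 2 * min(GROUP_RADII[group]) + 1


def score_matrix(seq: str, group: Group, sequence_id: str = "") -> ScoreMatrix:
    """Compute the five score tracks of *group* over the whole sequence.

    Raises ``SequenceError`` when even the smallest radius's window fits
    nowhere (every track empty).  Larger radii that do not fit yield fully
    undefined (NaN) tracks; the consensus stage then rejects the sequence
    because "4 of 5" needs all five scores.
    """
    if group not in GROUP_RADII:
        raise ValueError(f"group must be 'G1' or 'G2', got {group!r}")
    kd = _kd_array(seq)
    L = len(kd)
    need = min_length(group)
    if L < need:
        raise SequenceError(
            f"sequence {sequence_id or '<unnamed>'} has length {L}; group "
            f"{group} needs at least {need} residues"
        )
    radii = GROUP_RADII[group]
    out = np.full((len(radii), L), np.nan)
    for row, n in enumerate(radii):
        if L < 2 * n + 1:
            continue
        w = sinus_weights(n)
        # vectorised: for each offset k, following-minus-preceding difference
        centre = np.arange(n, L - n)
        acc = np.zeros(L - 2 * n)
        for k in range(1, n + 1):
            acc += w[k - 1] * (kd[centre + k] - kd[centre - k])
        out[row, n : L - n] = acc
    return ScoreMatrix(sequence_id=sequence_id, group=group, radii=radii, scores=out)
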