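"""Sign-consensus automaton and hydrophobic-pulse calling.

A position's five radius scores vote by sign.  When at least 4 of 5 are
strictly positive the automaton moves to (or stays in) the POSITIVE state;
when at least 4 of 5 are strictly negative it moves to NEGATIVE; any other
split — including ties caused by exact zeros, which count for neither side —
leaves the state unchanged.  The automaton starts NEGATIVE, so no pulse can
fire before the first decisive positive consensus.

A hydrophobic pulse is the first position of each maximal POSITIVE run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SequenceError
from .scoring import Group, ScoreMatrix, score_matrix

POSITIVE = 1
NEGATIVE = -1

#: votes required for a decisive consensus
_QUORUM = 4


@dataclass(frozen=True)
class ConsensusTrack:
    """Automaton state per position over the group's common defined range.

    ``states[p - start]`` is +1 (POSITIVE) or -1 (NEGATIVE) for sequence
    position ``p`` in ``[start, start + len(states) - 1]``.
    """

    sequence_id: str
    group: Group
    start: int  # 1-based sequence position of states[0]
    states: np.ndarray = field(repr=False)

    @property
    def end(self) -> int:
        return self.start + len(self.states) - 1


@dataclass(frozen=True)
class PulseTrack:
    """Called pulses plus the consensus and scores they came from.

    ``pulses`` are strictly increasing 1-based sequence positions; each is
    the first position of a maximal POSITIVE consensus run.
    """

    sequence_id: str
    group: Group
    pulses: tuple[int, ...]
    consensus: ConsensusTrack | None = None
    source_scores: ScoreMatrix | None = None


def pulse_positions(obj) -> tuple[int, ...]:
    """Positions from a PulseTrack or any iterable of ints (sorted)."""
    if isinstance(obj, PulseTrack):
        return obj.pulses
    return tuple(sorted(int(p) for p in obj))


def sign_consensus(matrix: ScoreMatrix) -> ConsensusTrack:
    """Run the 4-of-5 sign-consensus automaton over a score matrix."""
    if matrix.scores.shape[0] != 5:
        raise SequenceError(
            f"consensus needs 5 radius tracks, got {matrix.scores.shape[0]}"
        )
    lo, hi = matrix.common_range
    if lo > hi:
        raise SequenceError(
            f"sequence too short for group {matrix.group}: empty common range"
        )
    window = matrix.scores[:, lo - 1 : hi]
    if np.isnan(window).any():
        raise SequenceError("undefined scores inside the common range")
    pos = (window > 0).sum(axis=0)
    neg = (window < 0).sum(axis=0)
    decisive = np.where(pos >= _QUORUM, POSITIVE, np.where(neg >= _QUORUM, NEGATIVE, 0))
    # forward-fill the last decisive verdict; initial state NEGATIVE
    idx = np.arange(len(decisive))
    last = np.maximum.accumulate(np.where(decisive != 0, idx, -1))
    states = np.where(last >= 0, decisive[np.maximum(last, 0)], NEGATIVE).astype(np.int8)
    return ConsensusTrack(
        sequence_id=matrix.sequence_id, group=matrix.group, start=lo, states=states
    )


def call_pulses(consensus: ConsensusTrack, matrix: ScoreMatrix | None = None) -> PulseTrack:
    """Extract pulses: first position of each maximal POSITIVE run."""
    s = consensus.states
    if len(s) == 0:
        raise SequenceError("empty consensus track")
    starts = np.flatnonzero((s == POSITIVE) & (np.r_[NEGATIVE, s[:-1]] != POSITIVE))
    pulses = tuple(int(p) + consensus.start for p in starts)
    return PulseTrack(
        sequence_id=consensus.sequence_id,
        group=consensus.group,
        pulses=pulses,
        consensus=consensus,
        source_scores=matrix,
    )


def detect_hpulses(seq: str, group: Group, sequence_id: str = "") -> PulseTrack:
    """Full chain: score the sequence, form the consensus, call pulses.

    Deterministic: identical input always yields the identical pulse list.
    """
    matrix = score_matrix(seq, group, sequence_id=sequence_id)
    consensus = sign_consensus(matrix)
    return call_pulses(consensus, matrix)
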