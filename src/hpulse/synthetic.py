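"""Deterministic synthetic alpha-helical membrane proteins.

The generator renders the block architecture of a polytopic membrane
protein — polar loops alternating with hydrophobic membrane-spanning
segments — together with its ground-truth annotation, so every analysis in
the package can be exercised without structural downloads.

Defaults mirror the study conditions: membrane-spanning blocks of 21
residues (the length a straight helix needs to cross the bilayer), helices
extended 2 residues past the embedded segment on each side so the [A;B] and
[C;D] caps are non-empty, and strongly separated residue alphabets
(hydrophobic {I,L,V,F} vs polar {R,K,D,Q,S}) so pulse recovery is
unambiguous.  What the fixtures deliberately do not model: realistic
amino-acid composition, re-entrant loops, or kinked helices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import MembraneAnnotation
from .errors import SequenceError
from .scale import KD_SCALE


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic membrane protein.

    ``jitter`` shifts each planted helix extremity by a uniform integer in
    [-jitter, +jitter] (annotation only; the rendered sequence keeps its
    block structure).  Identical seeds give identical fixtures on every
    platform (all draws go through numpy's seeded PCG64 integer API).
    """

    n_tmh: int = 4
    tms_length: int = 21
    loop_length: int = 12
    helix_flank: int = 2
    hydrophobic_alphabet: tuple[str, ...] = ("I", "L", "V", "F")
    polar_alphabet: tuple[str, ...] = ("R", "K", "D", "Q", "S")
    jitter: int = 0
    interfacial_helix: bool = False
    interfacial_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tmh < 1 or self.tms_length < 1 or self.loop_length < 1:
            raise SequenceError("n_tmh, tms_length and loop_length must be positive")
        mean = lambda alpha: float(np.mean([KD_SCALE[a] for a in alpha]))  # noqa: E731
        if mean(self.hydrophobic_alphabet) <= mean(self.polar_alphabet):
            raise SequenceError(
                "hydrophobic alphabet must have higher mean KD than the polar one"
            )


@dataclass
class Fixture:
    sequence: str
    annotation: MembraneAnnotation
    truth: list[dict] = field(default_factory=list)  # planted events


def make_block_sequence(blocks: list[tuple[str, int]]) -> str:
    """Concatenate (residue, length) blocks into a sequence."""
    if not blocks:
        raise SequenceError("empty block list")
    out = []
    for residue, length in blocks:
        if residue not in KD_SCALE:
            raise SequenceError(f"non-canonical residue {residue!r} in block list")
        if length < 1:
            raise SequenceError(f"non-positive block length {length}")
        out.append(residue * length)
    return "".join(out)


def make_tm_protein(spec: FixtureSpec) -> Fixture:
    """Render a loop/TMS alternating protein with ground-truth annotation.

    Layout: loop, (TMS, loop) * n_tmh.  The annotation marks each TMS block
    as in_membrane, and as helical from ``flank`` residues before the block
    to ``flank`` after (clipped to the sequence and to loop midpoints so
    consecutive helices never touch).  With ``interfacial_helix=True`` a
    short hydrophobic helix lying in a loop is inserted between the first
    two TMHs.
    """
    rng = np.random.default_rng(spec.seed)
    hyd = spec.hydrophobic_alphabet
    pol = spec.polar_alphabet

    def draw(alpha, n):
        idx = rng.integers(0, len(alpha), size=n)
        return "".join(alpha[i] for i in idx)

    parts = [draw(pol, spec.loop_length)]
    tms_bounds = []
    pos = spec.loop_length
    for _ in range(spec.n_tmh):
        tms_bounds.append((pos + 1, pos + spec.tms_length))
        parts.append(draw(hyd, spec.tms_length))
        pos += spec.tms_length
        parts.append(draw(pol, spec.loop_length))
        pos += spec.loop_length
    seq = "".join(parts)
    L = len(seq)

    interfacial = None
    if spec.interfacial_helix and spec.n_tmh >= 2:
        # place a short hydrophobic helix in the middle of the first
        # inter-TMS loop; needs a loop long enough to hold it
        gap_lo = tms_bounds[0][1] + 1
        gap_hi = tms_bounds[1][0] - 1
        if gap_hi - gap_lo + 1 < spec.interfacial_length + 2:
            raise SequenceError(
                "loop too short to host the interfacial helix; increase loop_length"
            )
        mid = (gap_lo + gap_hi) // 2
        a = mid - spec.interfacial_length // 2
        b = a + spec.interfacial_length - 1
        seq = seq[: a - 1] + draw(hyd, spec.interfacial_length) + seq[b:]
        interfacial = (a, b)

    helical = np.zeros(L, dtype=bool)
    in_membrane = np.zeros(L, dtype=bool)
    truth = []
    prev_end = 0
    for i, (b, c) in enumerate(tms_bounds):
        in_membrane[b - 1 : c] = True
        ja = int(rng.integers(-spec.jitter, spec.jitter + 1)) if spec.jitter else 0
        jd = int(rng.integers(-spec.jitter, spec.jitter + 1)) if spec.jitter else 0
        a = max(b - spec.helix_flank + ja, prev_end + 2, 1)
        nxt = tms_bounds[i + 1][0] if i + 1 < len(tms_bounds) else L + spec.helix_flank + 2
        d = min(c + spec.helix_flank + jd, nxt - 2, L)
        helical[a - 1 : d] = True
        truth.append({"kind": "tmh", "A": a, "B": b, "C": c, "D": d})
        prev_end = d
    if interfacial:
        a, b = interfacial
        helical[a - 1 : b] = True
        truth.append({"kind": "interfacial", "start": a, "end": b})

    ann = MembraneAnnotation(
        sequence_id=f"synthetic-{spec.n_tmh}tmh-seed{spec.seed}",
        length=L,
        helical=helical,
        in_membrane=in_membrane,
    )
    return Fixture(sequence=seq, annotation=ann, truth=truth)
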