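"""Per-residue structural annotation of a membrane protein.

Each residue carries two independent boolean states: *helical* (is part of an
alpha-helix) and *in_membrane* (is inside the lipid bilayer).  Maximal runs of
these tracks define the alpha-helices and the transmembrane segments (TMS).
Kink positions, detected externally from 3D structures, are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError

Segment = tuple[int, int]  # 1-based inclusive (start, end)


def bool_runs(mask: np.ndarray) -> list[Segment]:
    """Maximal runs of True in *mask*, as 1-based inclusive intervals."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.r_[False, mask, False].astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


@dataclass(frozen=True)
class MembraneAnnotation:
    """Helical / membrane state tracks plus derived segments.

    Parameters
    ----------
    sequence_id : str
    length : int
        Number of residues.
    helical, in_membrane : ndarray of bool, shape (length,)
        ``helical[i-1]`` / ``in_membrane[i-1]`` refer to 1-based position i.
    kinks : tuple of int
        1-based kink positions; each must lie inside a helix.
    """

    sequence_id: str
    length: int
    helical: np.ndarray = field(repr=False)
    in_membrane: np.ndarray = field(repr=False)
    kinks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("helical", "in_membrane"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.length,):
                raise AnnotationError(
                    f"{name} track has shape {arr.shape}, expected ({self.length},)"
                )
        object.__setattr__(self, "kinks", tuple(int(k) for k in self.kinks))
        for k in self.kinks:
            if not (1 <= k <= self.length):
                raise AnnotationError(f"kink position {k} outside sequence 1..{self.length}")
            if not self.helical[k - 1]:
                raise AnnotationError(f"kink at position {k} lies outside every helix")

    @property
    def helices(self) -> list[Segment]:
        """Maximal helical runs, ordered."""
        return bool_runs(self.helical)

    @property
    def tms_list(self) -> list[Segment]:
        """Maximal membrane-embedded runs (transmembrane segments), ordered."""
        return bool_runs(self.in_membrane)

    def tm_context_mask(self, flank: int = 40) -> np.ndarray:
        """Boolean mask of residues within *flank* of any TMS (TMS +/- flank)."""
        mask = np.zeros(self.length, dtype=bool)
        for b, c in self.tms_list:
            mask[max(b - flank, 1) - 1 : min(c + flank, self.length)] = True
        return mask


def annotation_from_segments(
    sequence_id: str,
    length: int,
    helices: list[Segment],
    tms: list[Segment],
    kinks: tuple[int, ...] = (),
) -> MembraneAnnotation:
    """Build an annotation from interval lists (1-based inclusive)."""
    helical = np.zeros(length, dtype=bool)
    in_membrane = np.zeros(length, dtype=bool)
    for a, b in helices:
        if not (1 <= a <= b <= length):
            raise AnnotationError(f"helix ({a},{b}) outside sequence 1..{length}")
        helical[a - 1 : b] = True
    for a, b in tms:
        if not (1 <= a <= b <= length):
            raise AnnotationError(f"TMS ({a},{b}) outside sequence 1..{length}")
        in_membrane[a - 1 : b] = True
    return MembraneAnnotation(sequence_id, length, helical, in_membrane, kinks)
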