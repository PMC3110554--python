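"""Evaluation of G1 pulses against structural annotations.

Three analyses:

* nearest-pulse assignment — give every membrane-proximal helix extremity a
  unique G1 pulse and report the signed distances;
* event matching — classify each pulse by the nearest structural event
  (helix begin/end, TMS begin/end, kink) within a residue tolerance;
* multi-conformation reports — align sub-helix start positions observed in
  several crystal structures of one protein into rows, pair rows with
  computed G1 pulses, and derive conservation / false-positive statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MembraneAnnotation
from .pulses import PulseTrack, detect_hpulses, pulse_positions
from .topology import TM_FLANK

EVENT_TOLERANCE = 3  # residues

# ---------------------------------------------------------------------------
# extremity selection and nearest-pulse assignment


def membrane_helix_extremities(
    annotation: MembraneAnnotation,
    which: str = "begin",
    flank: int = TM_FLANK,
) -> list[int]:
    """Extremities of helices lying in or near the membrane.

    A helix qualifies when its distance to the closest TMS is at most
    *flank* residues.  ``which`` selects "begin", "end" or "both".
    """
    if which not in {"begin", "end", "both"}:
        raise ValueError(f"which must be 'begin', 'end' or 'both', got {which!r}")
    tms = annotation.tms_list
    out = []
    for a, b in annotation.helices:
        # distance between helix [a;b] and TMS [b2;c2]; 0 when they overlap
        near = any(max(b2 - b, a - c2, 0) <= flank for b2, c2 in tms)
        if not near:
            continue
        if which in {"begin", "both"}:
            out.append(a)
        if which in {"end", "both"}:
            out.append(b)
    return sorted(out)


@dataclass(frozen=True)
class Assignment:
    extremity: int
    kind: str
    pulse: int | None
    distance: int | None  # pulse - extremity (signed)


def assign_closest_pulses(
    extremities: Sequence[int],
    g1: PulseTrack,
    annotation: MembraneAnnotation | None = None,
    flank: int = TM_FLANK,
    kind: str = "helix-begin",
) -> tuple[list[Assignment], Counter]:
    """Greedy globally-nearest unique matching of extremities to pulses.

    Repeatedly takes the unassigned (extremity, pulse) pair with the smallest
    absolute distance; ties prefer the upstream pulse (negative signed
    distance), then the earlier extremity.  When *annotation* is given,
    pulses are restricted to the TM region (TMS +/- *flank*).  Every
    extremity receives a pulse whenever pulses outnumber extremities;
    otherwise the leftovers are reported unassigned.

    Returns the assignments (ordered by extremity) and a Counter of signed
    distances (the histogram).
    """
    pulses = list(pulse_positions(g1))
    if annotation is not None:
        region = annotation.tm_context_mask(flank)
        pulses = [p for p in pulses if region[p - 1]]
    exts = sorted(set(int(e) for e in extremities))
    pairs = sorted(
        (abs(p - e), 0 if p < e else 1, e, p)
        for e in exts
        for p in pulses
    )
    taken_e: dict[int, int] = {}
    taken_p: set[int] = set()
    for _, _, e, p in pairs:
        if e in taken_e or p in taken_p:
            continue
        taken_e[e] = p
        taken_p.add(p)
    assignments = []
    hist: Counter = Counter()
    for e in exts:
        p = taken_e.get(e)
        d = (p - e) if p is not None else None
        assignments.append(Assignment(extremity=e, kind=kind, pulse=p, distance=d))
        if d is not None:
            hist[d] += 1
    return assignments, hist


# ---------------------------------------------------------------------------
# event matching

_KIND_PRIORITY = {
    "helix-begin": 0,
    "helix-end": 0,
    "TMS-begin": 1,
    "TMS-end": 1,
    "kink": 2,
}


@dataclass
class EventMatchReport:
    """Per-pulse nearest-event classification under a tolerance."""

    tolerance: int
    matches: dict[int, tuple[str, int] | None]  # pulse -> (kind, distance)|None

    @property
    def n_pulses(self) -> int:
        return len(self.matches)

    @property
    def n_matched(self) -> int:
        return sum(1 for m in self.matches.values() if m is not None)

    def matched_fraction(self) -> float:
        return self.n_matched / self.n_pulses if self.matches else float("nan")

    def kind_fractions(self) -> dict[str, float]:
        """Percent of matched pulses per event kind (sums to 100)."""
        c = Counter(m[0] for m in self.matches.values() if m is not None)
        n = self.n_matched
        return {k: 100.0 * v / n for k, v in sorted(c.items())} if n else {}


def structural_events(annotation: MembraneAnnotation) -> list[tuple[int, str]]:
    """The five event kinds: helix begin/end, TMS begin/end, kinks."""
    events = []
    for a, b in annotation.helices:
        events.append((a, "helix-begin"))
        events.append((b, "helix-end"))
    for a, b in annotation.tms_list:
        events.append((a, "TMS-begin"))
        events.append((b, "TMS-end"))
    for k in annotation.kinks:
        events.append((k, "kink"))
    return events


def match_events(
    g1: PulseTrack,
    annotation: MembraneAnnotation,
    tolerance: int = EVENT_TOLERANCE,
) -> EventMatchReport:
    """Classify each pulse by the nearest structural event within tolerance.

    When several events tie at the same distance, helix extremities beat TMS
    extremities beat kinks.
    """
    events = structural_events(annotation)
    matches: dict[int, tuple[str, int] | None] = {}
    for p in pulse_positions(g1):
        best = None
        for pos, kind in events:
            d = pos - p
            if abs(d) > tolerance:
                continue
            key = (abs(d), _KIND_PRIORITY[kind], pos)
            if best is None or key < best[0]:
                best = (key, (kind, d))
        matches[p] = best[1] if best else None
    return EventMatchReport(tolerance=tolerance, matches=matches)


def proline_kink_stats(
    seq: str,
    kinks: Sequence[int],
    g1: PulseTrack,
    tolerance: int = EVENT_TOLERANCE,
) -> dict[str, int]:
    """Count prolines and G1 pulses within *tolerance* of any kink.

    Each proline / pulse is counted once even if several kinks are nearby.
    """
    kinks = sorted(set(int(k) for k in kinks))
    near = lambda x: any(abs(x - k) <= tolerance for k in kinks)  # noqa: E731
    prolines = [i for i, aa in enumerate(seq.upper(), start=1) if aa == "P"]
    return {
        "n_kinks": len(kinks),
        "n_prolines": len(prolines),
        "prolines_near_kinks": sum(1 for p in prolines if near(p)) if kinks else 0,
        "n_pulses": len(pulse_positions(g1)),
        "pulses_near_kinks": sum(1 for p in pulse_positions(g1) if near(p)) if kinks else 0,
    }


# ---------------------------------------------------------------------------
# multi-conformation reports

GROUP_RADIUS = 6   # max within-row spread of sub-helix starts
PAIR_RADIUS = 7    # max |pulse - nearest start| for row association


@dataclass
class StartRow:
    """One aligned row: at most one sub-helix start per structure."""

    starts: dict[str, int]  # structure id -> position

    @property
    def positions(self) -> list[int]:
        return sorted(self.starts.values())

    def distance_to(self, pulse: int) -> int:
        return min(abs(pulse - s) for s in self.positions)


def group_start_rows(
    starts_by_structure: Mapping[str, Sequence[int]],
    radius: int = GROUP_RADIUS,
) -> list[StartRow]:
    """Align per-structure start lists into rows.

    Agglomerative merging of adjacent clusters along the sequence, closest
    gap first, subject to two constraints: the merged row spans at most
    *radius* residues, and no structure contributes two starts to one row.
    The structure-uniqueness constraint is what keeps, e.g., a start shared
    by all conformations separate from a distinct nearby start seen in only
    two of them.
    """
    items = sorted(
        (int(p), s) for s, lst in starts_by_structure.items() for p in lst
    )
    clusters: list[list[tuple[int, str]]] = [[it] for it in items]

    def can_merge(a, b):
        if b[-1][0] - a[0][0] > radius:
            return False
        return not ({s for _, s in a} & {s for _, s in b})

    while True:
        best = None
        for i in range(len(clusters) - 1):
            a, b = clusters[i], clusters[i + 1]
            if can_merge(a, b):
                gap = b[0][0] - a[-1][0]
                if best is None or gap < best[0]:
                    best = (gap, i)
        if best is None:
            break
        i = best[1]
        clusters[i : i + 2] = [clusters[i] + clusters[i + 1]]
    return [StartRow(starts=dict((s, p) for p, s in c)) for c in clusters]


@dataclass
class ConformationTable:
    """Table-4-style report: aligned start rows vs computed G1 pulses."""

    structures: tuple[str, ...]
    rows: list[StartRow]
    pulses: tuple[int, ...]
    pulse_of_row: dict[int, int]  # row index -> pulse position
    row_of_pulse: dict[int, int]  # pulse position -> row index
    group_radius: int
    pair_radius: int

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def rows_in_all_structures(self) -> list[int]:
        return [
            i for i, r in enumerate(self.rows)
            if set(r.starts) == set(self.structures)
        ]

    def rows_pulse_associated(self) -> list[int]:
        return sorted(self.pulse_of_row)

    def false_positives(self, structure: str | None = None) -> list[int]:
        """Pulses not associated with a start (of *structure*, or of any)."""
        out = []
        for p in self.pulses:
            ri = self.row_of_pulse.get(p)
            if ri is None:
                out.append(p)
            elif structure is not None and structure not in self.rows[ri].starts:
                out.append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Render the table: one row per start row or orphan pulse."""
        records = []
        for i, r in enumerate(self.rows):
            rec = {s: r.starts.get(s) for s in self.structures}
            rec["pulse"] = self.pulse_of_row.get(i)
            rec["in_all"] = set(r.starts) == set(self.structures)
            rec["_order"] = min(r.positions)
            records.append(rec)
        for p in self.false_positives():
            rec = {s: None for s in self.structures}
            rec["pulse"] = p
            rec["in_all"] = False
            rec["_order"] = p
            records.append(rec)
        df = pd.DataFrame(records).sort_values("_order").drop(columns="_order")
        df = df.reset_index(drop=True)
        for col in (*self.structures, "pulse"):
            df[col] = df[col].astype("Int64")
        return df


def conformation_report(
    seq: str,
    starts_by_structure: Mapping[str, Sequence[int]],
    group_radius: int = GROUP_RADIUS,
    pair_radius: int = PAIR_RADIUS,
    pulse_track: PulseTrack | None = None,
) -> ConformationTable:
    """Align multi-structure sub-helix starts with computed G1 pulses.

    Starts are grouped into rows (see :func:`group_start_rows`); G1 pulses
    are computed on *seq* unless a precomputed track is supplied.  Pulses are
    then paired with rows in sequence order: each pulse claims the nearest
    still-unclaimed row whose closest start is within *pair_radius*
    (ties prefer the upstream row).  Rows left unclaimed are starts with no
    pulse support; pulses left unclaimed are candidate false positives.
    """
    track = pulse_track if pulse_track is not None else detect_hpulses(seq, "G1")
    rows = group_start_rows(starts_by_structure, radius=group_radius)
    pulse_of_row: dict[int, int] = {}
    row_of_pulse: dict[int, int] = {}
    for p in track.pulses:
        candidates = [
            (r.distance_to(p), min(r.positions), i)
            for i, r in enumerate(rows)
            if i not in pulse_of_row and r.distance_to(p) <= pair_radius
        ]
        if not candidates:
            continue
        _, _, i = min(candidates)
        pulse_of_row[i] = p
        row_of_pulse[p] = i
    return ConformationTable(
        structures=tuple(starts_by_structure),
        rows=rows,
        pulses=track.pulses,
        pulse_of_row=pulse_of_row,
        row_of_pulse=row_of_pulse,
        group_radius=group_radius,
        pair_radius=pair_radius,
    )
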