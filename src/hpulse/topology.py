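"""Transmembrane topology analyses built on G2 pulses.

Landmarks follow the A..H convention for a pair of successive transmembrane
helices: the first TMH spans [A;D] with its embedded segment (TMS) at [B;C],
and the next TMH spans [E;H] with TMS [F;G].  All positions are 1-based and
intervals are inclusive unless stated otherwise.

The module provides

* landmark derivation from a per-residue annotation,
* the successive-TMH pair filter and the localisation of G2 pulses within
  the inter-helix region,
* transmembrane-unit (TMU) segmentation: the region between two consecutive
  G2 pulses groups one TMH with its satellite helices,
* the pulse-vs-helix contingency analysis in TM / non-TM contexts,
* the classic 19-residue Kyte-Doolittle sliding-window average and the
  rescue analysis of TMS that lack a KD peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MembraneAnnotation, Segment
from .errors import SequenceError
from .pulses import PulseTrack, pulse_positions
from .scale import KD_SCALE, validate_sequence

#: defaults used across the analyses
MAX_LOOP = 40          # max residues between successive TMHs
TM_FLANK = 40          # TM context = TMS +/- this many residues
KD_WINDOW = 19         # classic hydropathy sliding window
KD_THRESHOLD = 1.6     # classic TMS-peak threshold


# ---------------------------------------------------------------------------
# landmarks


@dataclass(frozen=True)
class LandmarkFrame:
    """A..D landmarks of one TMH/TMS: helix [A;D] containing TMS [B;C]."""

    A: int
    B: int
    C: int
    D: int
    helixless: bool = False

    def __post_init__(self) -> None:
        if not self.helixless and not (self.A <= self.B <= self.C <= self.D):
            raise ValueError(f"landmarks out of order: {self}")


@dataclass(frozen=True)
class TMHPair:
    """Two successive frames passing the pair criteria, with analysis span.

    ``span`` runs from the midpoint of [B;C] to the midpoint of [F;G]
    (midpoint = floor of the interval mean).
    """

    first: LandmarkFrame
    second: LandmarkFrame
    span: tuple[int, int]

    @property
    def C(self) -> int:
        return self.first.C

    @property
    def D(self) -> int:
        return self.first.D

    @property
    def E(self) -> int:
        return self.second.A

    @property
    def F(self) -> int:
        return self.second.B


def _midpoint(a: int, b: int) -> int:
    return (a + b) // 2


def derive_landmarks(annotation: MembraneAnnotation) -> list[LandmarkFrame]:
    """One frame per TMS: the TMH [A;D] is the smallest interval covering
    every helix that intersects the TMS.

    A TMS intersected by no helix yields a frame flagged ``helixless``
    (A = B, D = C); such frames are excluded from pair analyses.
    """
    frames = []
    for b, c in annotation.tms_list:
        covering = [
            (ha, hb)
            for ha, hb in annotation.helices
            if ha <= c and hb >= b
        ]
        if covering:
            a = min(ha for ha, _ in covering)
            d = max(hb for _, hb in covering)
            frames.append(LandmarkFrame(A=a, B=b, C=c, D=d))
        else:
            frames.append(LandmarkFrame(A=b, B=b, C=c, D=c, helixless=True))
    return sorted(frames, key=lambda f: f.B)


def successive_pairs(
    frames: Sequence[LandmarkFrame],
    max_loop: int = MAX_LOOP,
) -> tuple[list[TMHPair], list[tuple[int, str]]]:
    """Filter consecutive frame pairs by the three pair criteria.

    A pair (first, second) is kept when the lengths of [C;D] and [E;F] are
    strictly positive (D > C and F > E) and the length of [D;E] is smaller
    than *max_loop* (E - D < max_loop); interval length is the coordinate
    difference.  Returns ``(pairs, rejected)`` where *rejected* lists
    ``(index_of_first_frame, reason)``.
    """
    usable = [f for f in frames if not f.helixless]
    pairs: list[TMHPair] = []
    rejected: list[tuple[int, str]] = []
    for i in range(len(usable) - 1):
        f1, f2 = usable[i], usable[i + 1]
        E = f2.A
        if f1.D >= E:
            rejected.append((i, "overlapping TMHs (D >= E)"))
            continue
        if f1.D <= f1.C:
            rejected.append((i, "length of [C;D] not strictly positive"))
            continue
        if f2.B <= f2.A:
            rejected.append((i, "length of [E;F] not strictly positive"))
            continue
        if E - f1.D >= max_loop:
            rejected.append((i, f"length of [D;E] not smaller than {max_loop}"))
            continue
        span = (_midpoint(f1.B, f1.C), _midpoint(f2.B, f2.C))
        pairs.append(TMHPair(first=f1, second=f2, span=span))
    return pairs, rejected


# ---------------------------------------------------------------------------
# G2 localisation (pulse position relative to the inter-helix landmarks)

#: classification labels
LOCUS_TMS = "TMS"
LOCUS_CD = "[C;D]"
LOCUS_DE = "[D;E]"
LOCUS_EF = "[E;F]"
LOCUS_NONE = "none"


@dataclass
class PairLocalization:
    pair: TMHPair
    selected: int | None          # the one retained pulse (sequence position)
    locus: str                    # classification of the retained pulse
    discarded: tuple[int, ...]    # surplus pulses in [C;F]


@dataclass
class LocalizationSummary:
    """Aggregate interval statistics (residue and pulse fractions) over all pairs."""

    n_pairs: int
    n_none: int
    n_tms: int
    n_between: int                 # selected pulses with locus in CD/DE/EF
    n_discarded: int
    residue_counts: dict[str, int]  # residues per interval, summed over pairs
    pulse_counts: dict[str, int]    # selected pulses per interval

    def residue_pct(self) -> dict[str, float]:
        total = sum(self.residue_counts.values())
        return {k: 100.0 * v / total for k, v in self.residue_counts.items()} if total else {}

    def pulse_pct(self) -> dict[str, float]:
        total = sum(self.pulse_counts.values())
        return {k: 100.0 * v / total for k, v in self.pulse_counts.items()} if total else {}


def _classify(p: int, pair: TMHPair) -> str:
    """Mutually exclusive locus of a pulse inside the pair's span.

    Boundary convention: C and F themselves are embedded residues (TMS);
    [C;D] means (C,D), [D;E] means [D,E), and [E;F] means [E,F) — position E
    belongs to [E;F], so the hot spot at E and E-1 falls in two distinct
    intervals.
    """
    C, D, E, F = pair.C, pair.D, pair.E, pair.F
    if p <= C or p >= F:
        return LOCUS_TMS
    if p < D:
        return LOCUS_CD
    if p < E:
        return LOCUS_DE
    return LOCUS_EF


def localize_g2(
    pairs: Sequence[TMHPair], g2: PulseTrack
) -> tuple[list[PairLocalization], LocalizationSummary]:
    """Classify each pair's G2 pulse into TMS / [C;D] / [D;E] / [E;F].

    When several pulses lie between C and F, the one closest to E is
    retained (ties break toward the earlier position) and the surplus is
    reported as discarded.  Pairs whose span holds no pulse at all are
    classified ``none``; pulses only inside a TMS yield locus ``TMS``.
    """
    g2_pos = pulse_positions(g2)
    per_pair: list[PairLocalization] = []
    residue_counts = {LOCUS_CD: 0, LOCUS_DE: 0, LOCUS_EF: 0}
    pulse_counts = {LOCUS_CD: 0, LOCUS_DE: 0, LOCUS_EF: 0}
    n_none = n_tms = n_between = n_disc = 0
    for pair in pairs:
        C, D, E, F = pair.C, pair.D, pair.E, pair.F
        residue_counts[LOCUS_CD] += D - C - 1
        residue_counts[LOCUS_DE] += E - D
        residue_counts[LOCUS_EF] += F - E
        lo, hi = pair.span
        in_span = [p for p in g2_pos if lo <= p <= hi]
        between = [p for p in in_span if C < p < F]
        in_tms = [p for p in in_span if p not in between]
        if between:
            selected = min(between, key=lambda p: (abs(p - E), p))
            locus = _classify(selected, pair)
            discarded = tuple(p for p in between if p != selected)
            n_between += 1
            pulse_counts[locus] += 1
        elif in_tms:
            selected = min(in_tms, key=lambda p: (abs(p - E), p))
            locus = LOCUS_TMS
            discarded = tuple(p for p in in_tms if p != selected)
            n_tms += 1
        else:
            selected, locus, discarded = None, LOCUS_NONE, ()
            n_none += 1
        n_disc += len(discarded)
        per_pair.append(PairLocalization(pair, selected, locus, discarded))
    summary = LocalizationSummary(
        n_pairs=len(per_pair),
        n_none=n_none,
        n_tms=n_tms,
        n_between=n_between,
        n_discarded=n_disc,
        residue_counts=residue_counts,
        pulse_counts=pulse_counts,
    )
    return per_pair, summary


# ---------------------------------------------------------------------------
# transmembrane units


@dataclass(frozen=True)
class TMU:
    """Sequence interval between two consecutive G2 pulses (or region ends).

    ``members`` lists the helices whose first residue falls inside the
    interval; a TMU typically holds one TMS-bearing TMH plus small
    surrounding helices.
    """

    start: int
    end: int
    members: tuple[Segment, ...] = ()


def segment_tmus(
    g2: PulseTrack,
    annotation: MembraneAnnotation,
    region: tuple[int, int] | None = None,
) -> list[TMU]:
    """Cut *region* (default: whole sequence) at every G2 pulse.

    ``k`` pulses produce ``k + 1`` ordered, non-overlapping intervals that
    tile the region; a pulse position starts a new TMU.  Pulses at the very
    start of the region introduce no empty interval.
    """
    lo, hi = region if region is not None else (1, annotation.length)
    cuts = sorted(p for p in pulse_positions(g2) if lo < p <= hi)
    bounds = [lo, *cuts, hi + 1]
    tmus = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a >= b:
            continue
        members = tuple(h for h in annotation.helices if a <= h[0] <= b - 1)
        tmus.append(TMU(start=a, end=b - 1, members=members))
    return tmus


def count_pulses_between_tmhs(
    pairs: Sequence[TMHPair],
    g2: PulseTrack,
    annotation: MembraneAnnotation,
) -> pd.DataFrame:
    """Cross-tabulate pulse count in [D;E] against helices inside [D;E].

    Rows: 0, 1, 2, ``>2`` pulses; columns: no helix / one helix / more than
    one helix strictly between the two TMHs.
    """
    rows = ["0", "1", "2", ">2"]
    cols = ["no helix", "one helix", ">1 helix"]
    table = pd.DataFrame(0, index=rows, columns=cols)
    g2_pos = pulse_positions(g2)
    for pair in pairs:
        D, E = pair.D, pair.E
        n_pulses = sum(1 for p in g2_pos if D <= p <= E)
        n_helices = sum(1 for a, b in annotation.helices if D < a and b < E)
        r = str(n_pulses) if n_pulses <= 2 else ">2"
        c = cols[min(n_helices, 2)]
        table.loc[r, c] += 1
    return table


# ---------------------------------------------------------------------------
# context association (pulse distribution vs amino-acid distribution)


@dataclass
class ContextTable:
    """2x2 pulse and residue counts per context, with association p-values.

    ``counts`` rows are (TM, helix) combinations; ``p_tm`` / ``p_non_tm``
    compare, within each context, the observed split of pulses between
    helical and non-helical residues to the split expected if pulses simply
    followed the amino-acid distribution (chi-square goodness of fit).  A
    context with no pulses or no residues has an undefined (NaN) p-value.
    """

    counts: pd.DataFrame
    p_tm: float
    p_non_tm: float


def _gof_p(pulse_counts: np.ndarray, residue_counts: np.ndarray) -> float:
    n = pulse_counts.sum()
    r = residue_counts.sum()
    if n == 0 or r == 0 or (residue_counts == 0).any():
        return float("nan")
    expected = residue_counts / r * n
    chi2 = float(((pulse_counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=len(pulse_counts) - 1))


def context_association(
    track: PulseTrack,
    annotation: MembraneAnnotation,
    flank: int = TM_FLANK,
) -> ContextTable:
    """Tabulate pulses and residues by (TM context, helical state).

    TM context = within *flank* residues of any TMS.  The attached p-values
    test whether pulses are distributed over helical vs non-helical residues
    in proportion to the residues themselves.
    """
    tm = annotation.tm_context_mask(flank)
    hel = annotation.helical
    pulse_mask = np.zeros(annotation.length, dtype=bool)
    for p in pulse_positions(track):
        pulse_mask[p - 1] = True
    rows = []
    cells = {}
    for tm_state in (True, False):
        for hel_state in (True, False):
            sel = (tm == tm_state) & (hel == hel_state)
            cells[(tm_state, hel_state)] = (
                int((pulse_mask & sel).sum()),
                int(sel.sum()),
            )
            rows.append(
                {
                    "tm": "yes" if tm_state else "no",
                    "helix": "yes" if hel_state else "no",
                    "pulses": cells[(tm_state, hel_state)][0],
                    "residues": cells[(tm_state, hel_state)][1],
                }
            )
    counts = pd.DataFrame(rows)
    p_tm = _gof_p(
        np.array([cells[(True, True)][0], cells[(True, False)][0]]),
        np.array([cells[(True, True)][1], cells[(True, False)][1]]),
    )
    p_non = _gof_p(
        np.array([cells[(False, True)][0], cells[(False, False)][0]]),
        np.array([cells[(False, True)][1], cells[(False, False)][1]]),
    )
    return ContextTable(counts=counts, p_tm=p_tm, p_non_tm=p_non)


# ---------------------------------------------------------------------------
# classic Kyte-Doolittle window and the rescue analysis


@dataclass(frozen=True)
class KdProfile:
    """Centred sliding-window KD averages (NaN where the window overhangs)."""

    averages: np.ndarray = field(repr=False)
    window: int = KD_WINDOW
    threshold: float = KD_THRESHOLD

    def has_peak(self, start: int, end: int) -> bool:
        """True if any defined position in [start;end] exceeds the threshold."""
        seg = self.averages[start - 1 : end]
        return bool(np.any(seg[~np.isnan(seg)] > self.threshold))


def kd_classic(seq: str, window: int = KD_WINDOW, threshold: float = KD_THRESHOLD) -> KdProfile:
    """Plain centred mean of KD values over a sliding window (default 19).

    A position whose average exceeds the threshold (default 1.6) marks a
    hydrophobic peak; a region "has a peak" when any of its positions does.
    """
    seq = validate_sequence(seq)
    L = len(seq)
    if L < window:
        raise SequenceError(
            f"sequence length {L} is shorter than the KD window ({window})"
        )
    if window % 2 != 1:
        raise ValueError("KD window must be odd (centred window)")
    kd = np.array([KD_SCALE[aa] for aa in seq])
    half = window // 2
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    averages = np.full(L, np.nan)
    averages[half : L - half] = means
    return KdProfile(averages=averages, window=window, threshold=threshold)


@dataclass(frozen=True)
class TmsRescue:
    tms: Segment
    peaked: bool
    rescued: bool | None  # None when the TMS is peaked (rescue not needed)


def undetected_tms_rescue(
    annotation: MembraneAnnotation,
    kd_profile: KdProfile,
    g2: PulseTrack,
) -> list[TmsRescue]:
    """For each TMS without a KD peak, ask whether a G2 pulse precedes it.

    A TMS is *rescued* when a G2 pulse lies strictly between the end of the
    preceding TMS (or the sequence start) and the end of this TMS.
    """
    out = []
    prev_end = 0
    for b, c in annotation.tms_list:
        peaked = kd_profile.has_peak(b, c)
        if peaked:
            out.append(TmsRescue(tms=(b, c), peaked=True, rescued=None))
        else:
            rescued = any(prev_end < p < c for p in pulse_positions(g2))
            out.append(TmsRescue(tms=(b, c), peaked=False, rescued=rescued))
        prev_end = c
    return out
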