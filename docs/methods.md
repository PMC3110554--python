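# Methods

## Model

A hydrophobic pulse formalises "hydrophobicity starts rising here".  The
per-position statistic is a two-sided, sinus-weighted contrast of
Kyte–Doolittle hydropathies:

    score(i, n) = Σ_{k=1..n} w_n(k) · [KD(AA(i+k)) − KD(AA(i−k))],
    w_n(k) = sin(k·π/(n+1))

The half-sine weight rises from the centre outward to a maximum mid-window
and falls back to (near) zero at the window edge, so the contrast is driven
by the mid-range of each flank rather than by the residues immediately
adjacent to *i* or at the window rim.  The central residue carries no
weight; the score is therefore exactly antisymmetric under sequence
reversal, zero on homopolymers, and local (touching a residue more than
*n* positions away cannot change it).  The weight form was fixed by
requiring the full detection chain to reproduce, exactly and
simultaneously, all 27 reference G1 pulse positions of the lactose
permease case study; no other candidate side-symmetric form
(sin kπ/2n, sin kπ/(2n+1), cosine ramps, uniform) does.

Radii are grouped: G1 = {2,3,4,5,6} for single-turn events (n = 2 is the
shortest stretch that can adopt a helical hydrogen-bond pattern) and
G2 = {12,…,16} for TM-helix-scale events (a straight membrane-crossing
helix needs ≈ 21 residues ⇒ n ≈ 10; windows beyond n = 16 can straddle two
TM helices, whose loops can be as short as one or two residues).
Intermediate radii blend the two regimes and are not computed.

## Consensus automaton

Per position the five radius scores vote by strict sign; exact zeros
abstain.  ≥ 4 positive votes ⇒ state POSITIVE, ≥ 4 negative ⇒ NEGATIVE,
otherwise the automaton holds its state.  The automaton starts NEGATIVE so
that a pulse can only fire at the first *decisive* positive consensus; a
POSITIVE start state would fabricate a pulse at the track edge.  The
consensus exists only on the common defined range [max(n)+1, L−max(n)]:
"4 of 5" is meaningless where fewer than five scores exist.  Pulses are
the first positions of maximal POSITIVE runs, reported in 1-based sequence
coordinates.  The start-state and hold-rule conventions are validated by
the case study: starting POSITIVE would drop the first reference LacY
pulse (position 7), and any emit-on-indecision variant changes the list.

## Landmarks and conventions

All positions are 1-based, intervals inclusive.  For one TM helix the
frame is A ≤ B ≤ C ≤ D: [B;C] the embedded segment (TMS, from the membrane
annotation), [A;D] the smallest interval covering every helix that
intersects the TMS (a TMH can comprise several α-helices).  For successive
frames the second helix contributes E..H.  Pair analyses keep consecutive
frames with strictly positive [C;D] and [E;F] lengths and [D;E] length
< 40, where interval length is the coordinate difference (so C = D is
excluded, and E − D = 40 is excluded).  Analysis spans run from the
midpoint of [B;C] to the midpoint of [F;G]; midpoints are floor(mean),
deterministic for even-length segments.

Locus classification of a pulse between two helices is mutually exclusive:
TMS for p ≤ C or p ≥ F, (C;D) → "[C;D]", [D;E) → "[D;E]", [E;F) → "[E;F]".
Position E belongs to [E;F] and E−1 to [D;E], so the two hot-spot
positions fall in distinct intervals and both are countable.  When several
pulses lie between C and F only the one closest to E is retained (ties go
to the earlier position); the surplus is reported as discarded.  The
closest-to-E selection rule is a package choice (E is where pulses
concentrate) and is exposed in the
per-pair report so alternatives can be audited.

Transmembrane units tile the analysis region: k pulses cut it into k+1
ordered, gap-free intervals; helices belong to the TMU containing their
first residue.

The TM context is TMS ± 40 residues.  The association between pulses and
helical state within a context is tested by a chi-square goodness-of-fit
of the observed pulse split (helical vs not) against the split expected if
pulses followed the residue distribution; the test identity (and its
df = 1 approximation) is a package decision.
Contexts with no pulses or empty residue classes yield an undefined
(NaN) p-value rather than a fabricated one.

## G1 evaluation

Helix extremities are taken from helices whose distance to the closest TMS
is ≤ 40 residues; assignment of pulses to extremities is greedy
globally-nearest with each pulse used at most once, ties preferring the
upstream pulse (helix N-caps precede the helix).  Event matching accepts a
3-residue error and classifies by the nearest event, ties ordered helix
extremity > TMS extremity > kink.

Multi-conformation reports align per-structure sub-helix starts into rows
by constrained agglomerative clustering: adjacent clusters merge closest
gap first, subject to a row span ≤ 6 residues (the largest within-row
spread observed in the case-study table) and to no structure contributing
two starts to one row.  The structure-uniqueness constraint is essential:
a start shared by all five structures two residues from a distinct start
seen in two structures must not collapse into one row.  Pulses are then
paired to rows in sequence order, each claiming the nearest unclaimed row
whose closest start lies within 7 residues (the largest pulse–start
distance the case-study pairing exhibits; both radii are configurable).
A plain globally-greedy pairing was rejected because it mispairs
neighbouring rows ~8 residues apart whenever a pulse sits between them.
False positives against one structure are pulses whose row lacks a start
from that structure (or that have no row); against all conformations,
pulses with no row at all.

## Classic KD comparison

The reference hydropathy scan is the unweighted centred mean over a
19-residue window with a peak threshold of 1.6 KD units.  A TMS with no
position above threshold is "undetected"; it is *rescued* when a G2 pulse
lies strictly between the end of the preceding TMS (or the sequence start)
and its own end.

## Synthetic fixtures

The generator renders polar loops (default 12 residues, alphabet
{R,K,D,Q,S}) alternating with hydrophobic membrane blocks (default 21
residues — the membrane-crossing helix length — alphabet {I,L,V,F}),
helices extended 2 residues beyond each block so the [A;B]/[C;D] caps are
non-empty, optional 8-residue interfacial helices mid-loop, and optional
integer jitter on planted helix caps.  Draws go through numpy's seeded
PCG64 integer API, so identical seeds give identical fixtures on any
platform.  The fixtures emulate block architecture and KD contrast only:
they have unrealistic residue composition, no kinks, no re-entrant loops,
and loops far more polar than real ones.  Tests passing on them show the
machinery is correct, not that real proteins behave this cleanly — the
real-data behaviour is represented by the bundled lactose permease study.

## Numerical choices

Scores are float64; undefined positions are NaN, never zero.  Exact zero
scores abstain from the consensus vote (a zero is neither a rise nor a
fall).  Non-canonical residues (B, J, O, U, X, Z) are rejected with the
offending position — imputing a hydropathy would silently shift pulses.
CLI output fixes scores to 4 decimals and keeps stable row order, making
runs byte-reproducible.

## Problem sizes

The test suite and the acceptance script use desk-scale problems chosen to
exercise every code path densely: 200 random 50-mers for the scoring
properties, 500 random sign tables for the consensus oracle, 20 synthetic
4-helix proteins for TMS-separation recovery, 100 jittered fixtures for
assignment accuracy, and 100 replicates of 60 uniform pulses on a
1000-residue annotation for the null calibration of the association test.

## Known limitations

* Sidedness (cytoplasmic vs extracellular) is out of scope.
* Kinks are inputs (from external geometry analysis), never detected.
* 3₁₀ helices are not structural events; an opt-in STRIDE flag can merge
  leading/trailing 3₁₀ turns into adjacent α-helices for sensitivity
  analysis.
* Pulse intensity/length descriptors carry no validated discriminative
  signal and are not exposed.
* Structures with unresolved loops: annotations keep their gaps; scoring
  is sequence-based, and the mapping between the two must be explicit
  rather than renumbered.
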