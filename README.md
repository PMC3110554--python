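# hpulse — Hydrophobic Pulse Predictor

`hpulse` analyses the primary sequence of α-helical integral membrane
proteins through *hydrophobic pulses*: positions where hydrophobicity starts
to rise, detected from sinus-weighted Kyte–Doolittle (KD) hydropathy
variation at two window scales.  It is aimed at structural bioinformaticians
studying transmembrane (TM) topology: where classic hydropathy scans ask
"which residues are embedded?", pulse analysis asks "where does the membrane
architecture *change*?" — which turns out to mark helix boundaries, kinks
and the partitioning of a sequence into transmembrane units.

## The score and the automaton

For a residue at position *i* and a window radius *n*, the
hydrophobicity-variation score is the difference between the sinus-weighted
hydropathy of the *n* residues following *i* and that of the *n* residues
preceding it:

    score(i, n) = Σ_{k=1..n} sin(k·π/(n+1)) · [ KD(AA(i+k)) − KD(AA(i−k)) ]

The score involves 2·n+1 residues, is positive where hydrophobicity rises,
and is undefined wherever the window overhangs the sequence.  Two groups of
five radii are scored: **G1** (n = 2…6), resolving single-turn structural
events, and **G2** (n = 12…16), resolving TM-helix-scale events (a
membrane-spanning helix is ≈ 21 residues, n ≈ 10).

A finite-state automaton turns the five radius tracks of a group into a
sign consensus: ≥ 4 of 5 scores > 0 switches the state to POSITIVE, ≥ 4 of
5 < 0 switches it to NEGATIVE, anything else holds the current state
(initial state NEGATIVE; exact zeros vote for neither side).  A
**hydrophobic pulse** (HPulse) is the first position of each POSITIVE run.

On top of pulse detection the package implements the downstream analyses:
landmark frames (helix [A;D] containing TM segment [B;C]), localisation of
G2 pulses between successive TM helices, segmentation into transmembrane
units (TMUs), pulse-vs-helix contingency tables, the classic 19-residue
KD window comparison, and the evaluation of G1 pulses against helix
extremities, TMS boundaries and kinks — including multi-conformation
reports for proteins crystallized in several states.

## Worked example

The bundled case study is *E. coli* lactose permease (LacY), crystallized in
five conformations (PDB 1PV6, 1PV7, 2V8N, 2CFP, 2CFQ — the construct
carries the C154G mutation):

```python
from hpulse import detect_hpulses, conformation_report
from hpulse.data import load_lacy_1pv6, load_lacy_subhelix_starts

seq = load_lacy_1pv6()
print(detect_hpulses(seq, "G1").pulses[:6])   # (7, 27, 43, 61, 74, 82)

rep = conformation_report(seq, load_lacy_subhelix_starts())
print(len(rep.rows_in_all_structures()))       # 10
print(len(rep.rows_pulse_associated()))        # 25  (of 27 start rows)
print(len(rep.false_positives("1PV6")))        # 11  (of 27 pulses)
print(len(rep.false_positives()))              # 2
```

Reading: the five structures exhibit 27 distinct sub-helix start rows, 10
of them present in every conformation; 25/27 (92.6 %) lie within 7 residues
of a computed G1 pulse.  Judged against the single structure 1PV6, 11/27
pulses (40.7 %) look like false positives — but only 2/27 (7.4 %) remain
unsupported once all five conformations are considered: a pulse that is
"wrong" in one channel state is usually a real sub-helix start in another.

Run `python examples/01_lacy_pulses.py` … `05_simulate_and_evaluate.py` for
narrative walk-throughs of each capability, or use the CLI:

```sh
hpp pulses --group G2 my_proteins.fasta
hpp simulate --n-tmh 4 --seed 7 && hpp evaluate fixture.annotation.tsv
```

## Layout

- `src/hpulse/scale.py`, `scoring.py` — KD scale and variation scores
- `src/hpulse/pulses.py` — sign-consensus automaton, pulse calling
- `src/hpulse/topology.py` — landmarks, pairs, TMUs, KD comparison
- `src/hpulse/evaluate.py` — G1 evaluation and conformation reports
- `src/hpulse/formats.py` — FASTA / STRIDE / PDBTM XML / TSV I/O
- `src/hpulse/synthetic.py` — deterministic synthetic IMP generator
- `src/hpulse/cli.py` — the `hpp` command
- `docs/methods.md` — modelling assumptions, conventions, limitations
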