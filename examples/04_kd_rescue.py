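"""Rescue a weakly hydrophobic membrane segment missed by the classic scan.

The classic Kyte-Doolittle criterion calls a membrane segment where a
19-residue window average exceeds 1.6.  A mildly hydrophobic segment (here
alternating Met/Ser, window mean ~0.6) fails that test, yet the *rise* of
hydrophobicity at its start still produces a G2 pulse — which is how such
segments can be recovered.
"""

from hpulse import annotation_from_segments, detect_hpulses, kd_classic, undetected_tms_rescue

seq = (
    "S" * 15 + "I" * 21 + "S" * 15      # strong TMS 16-36
    + "MS" * 10 + "M"                   # weak TMS 52-72
    + "S" * 15 + "I" * 21 + "S" * 15    # strong TMS 88-108
)
tms = [(16, 36), (52, 72), (88, 108)]
ann = annotation_from_segments("demo", len(seq), tms, tms)

profile = kd_classic(seq)
g2 = detect_hpulses(seq, "G2")
print(f"G2 pulses: {list(g2.pulses)}")
for r in undetected_tms_rescue(ann, profile, g2):
    status = "KD peak" if r.peaked else (
        "no KD peak, rescued by a preceding G2 pulse" if r.rescued
        else "no KD peak, NOT rescued"
    )
    print(f"TMS [{r.tms[0]};{r.tms[1]}]: {status}")
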