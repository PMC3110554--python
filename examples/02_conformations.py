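"""Compare G1 pulses with sub-helix starts across five LacY crystal forms.

Lactose permease was crystallized in five conformations (1PV6, 1PV7, 2V8N,
2CFP, 2CFQ).  Aligning the observed sub-helix start positions across the
structures and pairing each computed G1 pulse with the nearest start row
shows that pulses flagged "false positive" against a single structure are
mostly real starts in another conformation.
"""

from hpulse import conformation_report
from hpulse.data import load_lacy_1pv6, load_lacy_subhelix_starts

seq = load_lacy_1pv6()
starts = load_lacy_subhelix_starts()
rep = conformation_report(seq, starts)

print(rep.to_frame().to_string(index=False))

n_rows, n_pulses = rep.n_rows, len(rep.pulses)
assoc = len(rep.rows_pulse_associated())
conserved = len(rep.rows_in_all_structures())
print(f"\nstart rows: {n_rows}   computed G1 pulses: {n_pulses}")
print(f"rows present in all five structures: {conserved}")
print(f"rows associated with a pulse: {assoc}/{n_rows} "
      f"({100 * assoc / n_rows:.1f}%)")
for s in starts:
    fp = len(rep.false_positives(s))
    print(f"pulses unsupported by {s} alone: {fp}/{n_pulses} "
          f"({100 * fp / n_pulses:.1f}%)")
fp_all = len(rep.false_positives())
print(f"pulses unsupported by every conformation: {fp_all}/{n_pulses} "
      f"({100 * fp_all / n_pulses:.1f}%)")
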