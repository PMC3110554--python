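"""Bundled case-study data.

* ``lacy_1pv6.fasta`` — Escherichia coli lactose permease (LacY) as
  crystallized: the C154G construct of PDB 1PV6/1PV7/2CFP/2CFQ.  This is the
  sequence the multi-conformation case study runs on.
* ``lacy_p02920.fasta`` — the wild-type LacY sequence (UniProt P02920);
  differs from the construct only at position 154 (C vs G).
* ``lacy_subhelix_starts.tsv`` — sub-helix start positions observed after
  STRIDE analysis of the five LacY crystal structures (structure_id, start).
"""

from __future__ import annotations

from importlib import resources

from ..formats import read_fasta, read_starts_tsv


def _path(name: str):
    return resources.files(__package__) / name


def load_lacy_1pv6() -> str:
    """Sequence of the crystallized LacY C154G construct (417 residues)."""
    return next(iter(read_fasta(_path("lacy_1pv6.fasta")).values()))


def load_lacy_wildtype() -> str:
    """Wild-type LacY sequence (UniProt P02920)."""
    return next(iter(read_fasta(_path("lacy_p02920.fasta")).values()))


def load_lacy_subhelix_starts() -> dict[str, list[int]]:
    """Per-structure sub-helix start positions for the five LacY models."""
    return read_starts_tsv(_path("lacy_subhelix_starts.tsv"))
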