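"""Readers and writers for the formats the tool touches.

Sequences arrive as FASTA (via Bio.SeqIO).  Per-residue structural states
come either from STRIDE output (helical states), from PDBTM XML (membrane
states), or from the package's own annotation TSV, which is the canonical
exchange format:

    sequence_id  position  residue  helical  in_membrane

with 1-based contiguous positions.  Kink positions travel in a two-column
TSV (sequence_id, position).  All readers validate loudly: silent coercion
of a malformed annotation would shift every downstream analysis.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import MembraneAnnotation
from .errors import AnnotationError, FormatError

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> upper-cased sequence mapping.

    Duplicate ids, empty records and non-alphabetic residue characters are
    rejected with messages naming the offender.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {record.id!r}")
        for i, ch in enumerate(seq, start=1):
            if not ch.isalpha():
                raise FormatError(
                    f"{path}: non-alphabetic character {ch!r} at position {i} "
                    f"of record {record.id!r}"
                )
        out[record.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# STRIDE

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def read_stride(
    path: str | Path,
    chain: str | None = None,
    merge_310: bool = False,
) -> dict:
    """Parse STRIDE ASG records into per-residue helical states.

    Only the alpha-helix state 'H' counts as helical; 3-10 helices ('G') do
    not, because short 3-10 turns habitually cap alpha-helices and would
    blur their extremities.  With ``merge_310=True``, 'G' runs immediately
    adjacent to an 'H' run are folded into it (sensitivity analysis only).

    Returns ``{"helical": bool array, "residues": str, "positions": array}``
    where positions are the 1-based ordinal residue numbers of the ASG
    records (author numbering is preserved in the ``author`` array).
    """
    path = Path(path)
    rows = []
    chains = set()
    for line in path.read_text().splitlines():
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}: malformed ASG line: {line!r}")
        _, resname, ch, author_num, ordinal, code = fields[:6]
        chains.add(ch)
        rows.append((ch, resname, author_num, int(ordinal), code))
    if not rows:
        raise FormatError(f"{path}: no ASG records found (missing ASG section?)")
    if chain is None:
        if len(chains) > 1:
            raise FormatError(
                f"{path}: multiple chains found ({', '.join(sorted(chains))}); "
                "pass chain=... to select one"
            )
        chain = next(iter(chains))
    elif chain not in chains:
        raise FormatError(
            f"{path}: chain {chain!r} not present (found {', '.join(sorted(chains))})"
        )
    rows = [r for r in rows if r[0] == chain]
    positions = np.array([r[3] for r in rows])
    codes = [r[4] for r in rows]
    helical = np.array([c == "H" for c in codes])
    if merge_310:
        # fold leading/trailing 3-10 runs into the adjacent alpha-helix
        n = len(codes)
        changed = True
        while changed:
            changed = False
            for i in range(n):
                if codes[i] == "G" and not helical[i]:
                    if (i > 0 and helical[i - 1]) or (i + 1 < n and helical[i + 1]):
                        helical[i] = True
                        changed = True
    residues = "".join(_THREE_TO_ONE.get(r[1], "X") for r in rows)
    author = np.array([r[2] for r in rows])
    return {
        "helical": helical,
        "residues": residues,
        "positions": positions,
        "author": author,
        "chain": chain,
    }


# ---------------------------------------------------------------------------
# PDBTM XML

_PDBTM_NS = "{http://pdbtm.enzim.hu}"


def read_pdbtm(path: str | Path, chain: str | None = None) -> dict:
    """Parse PDBTM XML into per-residue membrane states.

    Residues inside REGION elements typed 'H' (alpha-helical membrane
    segment) are in_membrane; every other region type (loops, membrane
    interface, unstructured, ...) is not.  Returns ``{"in_membrane": bool
    array, "length": L, "chain": id}`` indexed by the XML seq positions.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise FormatError(f"{path}: malformed XML: {exc}") from None
    root = tree.getroot()

    def findall(elem, tag):
        return elem.findall(f"{_PDBTM_NS}{tag}") or elem.findall(tag)

    chains = {}
    for ch in findall(root, "CHAIN"):
        cid = ch.attrib.get("CHAINID", "?")
        regions = [
            (
                int(r.attrib["seq_beg"]),
                int(r.attrib["seq_end"]),
                r.attrib.get("type", "?"),
            )
            for r in findall(ch, "REGION")
        ]
        chains[cid] = regions
    if not chains:
        raise FormatError(f"{path}: no CHAIN elements found")
    if chain is None:
        if len(chains) > 1:
            raise FormatError(
                f"{path}: multiple chains ({', '.join(sorted(chains))}); "
                "pass chain=... to select one"
            )
        chain = next(iter(chains))
    elif chain not in chains:
        raise FormatError(
            f"{path}: chain {chain!r} not present (found {', '.join(sorted(chains))})"
        )
    regions = chains[chain]
    length = max((e for _, e, _ in regions), default=0)
    mask = np.zeros(length, dtype=bool)
    n_h = 0
    for beg, end, rtype in regions:
        if rtype == "H":
            mask[beg - 1 : end] = True
            n_h += 1
    if n_h == 0:
        warnings.warn(f"{path}: chain {chain} has no membrane (type H) regions")
    return {"in_membrane": mask, "length": length, "chain": chain}


def check_position_consistency(
    seq: str, residues: str, positions: np.ndarray, source: str = "annotation"
) -> None:
    """Verify annotated residue letters against the FASTA sequence.

    Raises ``AnnotationError`` naming the first disagreeing position.  Use
    after reading STRIDE output alongside the sequence the scores run on.
    """
    for pos, aa in zip(positions, residues):
        if pos < 1 or pos > len(seq):
            raise AnnotationError(
                f"{source}: position {int(pos)} outside sequence 1..{len(seq)}"
            )
        if seq[pos - 1] != aa:
            raise AnnotationError(
                f"{source}: residue mismatch at position {int(pos)}: "
                f"sequence has {seq[pos - 1]!r}, annotation has {aa!r}"
            )


# ---------------------------------------------------------------------------
# annotation TSV (canonical exchange format)

_ANNOT_COLS = ["sequence_id", "position", "residue", "helical", "in_membrane"]


def read_annotation_tsv(path: str | Path) -> dict[str, tuple[str, MembraneAnnotation]]:
    """Read the canonical annotation TSV.

    Returns ``{sequence_id: (sequence, MembraneAnnotation)}``.  Positions
    must be contiguous 1..L per sequence; a gap is an error naming the first
    missing position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"residue": str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; expected {_ANNOT_COLS}")
    out = {}
    for sid, sub in df.groupby("sequence_id", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(pos, expected):
            bad = int(expected[pos != expected][0]) if len(pos) == len(expected) else int(
                next(e for e, p in zip(expected, list(pos) + [None]) if p != e)
            )
            raise FormatError(
                f"{path}: positions of {sid!r} not contiguous 1..L "
                f"(first problem at position {bad})"
            )
        seq = "".join(sub["residue"])
        ann = MembraneAnnotation(
            sequence_id=str(sid),
            length=len(seq),
            helical=sub["helical"].to_numpy().astype(bool),
            in_membrane=sub["in_membrane"].to_numpy().astype(bool),
        )
        out[str(sid)] = (seq, ann)
    return out


def write_annotation_tsv(
    entries: Mapping[str, tuple[str, MembraneAnnotation]], path: str | Path
) -> None:
    """Write the canonical annotation TSV (round-trip stable)."""
    records = []
    for sid, (seq, ann) in entries.items():
        if len(seq) != ann.length:
            raise AnnotationError(
                f"sequence {sid!r}: sequence length {len(seq)} != "
                f"annotation length {ann.length}"
            )
        for i, aa in enumerate(seq, start=1):
            records.append(
                {
                    "sequence_id": sid,
                    "position": i,
                    "residue": aa,
                    "helical": int(ann.helical[i - 1]),
                    "in_membrane": int(ann.in_membrane[i - 1]),
                }
            )
    pd.DataFrame(records, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def read_kinks_tsv(path: str | Path) -> dict[str, list[int]]:
    """Two-column TSV (sequence_id, position) -> id -> sorted positions."""
    df = pd.read_csv(path, sep="\t")
    if not {"sequence_id", "position"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns sequence_id, position")
    return {
        str(sid): sorted(int(p) for p in sub["position"])
        for sid, sub in df.groupby("sequence_id", sort=False)
    }


def read_starts_tsv(path: str | Path) -> dict[str, list[int]]:
    """Two-column TSV (structure_id, start) -> structure -> sorted starts."""
    df = pd.read_csv(path, sep="\t")
    if not {"structure_id", "start"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns structure_id, start")
    return {
        str(sid): sorted(int(p) for p in sub["start"])
        for sid, sub in df.groupby("structure_id", sort=False)
    }


# ---------------------------------------------------------------------------
# results


def write_results(obj, path: str | Path, fmt: str = "tsv") -> None:
    """Write a DataFrame (tsv/json) or any JSON-serialisable object (json).

    Output is deterministic: stable row order is the caller's contract,
    column order is preserved, JSON keys keep insertion order.
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        if fmt == "tsv":
            obj.to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            path.write_text(
                json.dumps(obj.to_dict(orient="records"), indent=2, default=_js)
                + "\n"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")
    else:
        if fmt != "json":
            raise ValueError(f"objects of type {type(obj).__name__} require json format")
        path.write_text(json.dumps(obj, indent=2, default=_js) + "\n")


def _js(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
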