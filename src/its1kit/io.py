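"""Readers/writers for FASTA, xfasta, Vienna and Newick files.

xfasta is the 4SALE-style dialect: per entry a header, a sequence block and
a structure block of equal length, with '-' permitted at identical positions
in both.  Vienna is header / sequence / dot-bracket (optionally with the
free energy in parentheses).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .records import Record, validate_dotbracket

_STRUCT_RE = re.compile(r"^[().\-]+$")


def read_fasta(path) -> list[Record]:
    """Read a FASTA file into a list of :class:`Record`.

    Duplicate IDs and empty sequences are errors; lowercase is upcased and
    T is normalized to U (remembered per record).
    """
    records: list[Record] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        if len(entry.seq) == 0:
            raise ValueError(f"empty sequence for record {entry.id!r} in {path}")
        records.append(Record.from_raw(entry.id, str(entry.seq)))
    return records


def write_fasta(records: Iterable[Record], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.output_seq
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _entry_blocks(path) -> list[tuple[str, list[str]]]:
    entries: list[tuple[str, list[str]]] = []
    header = None
    lines: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, lines))
                header = line[1:].split()[0]
                lines = []
            else:
                if header is None:
                    raise ValueError(f"{path}: data before first header")
                lines.append(line)
        if header is not None:
            entries.append((header, lines))
    return entries


def read_xfasta(path) -> list[Record]:
    """Read 4SALE-style xfasta: sequence block then structure block per entry."""
    records: list[Record] = []
    seen: set[str] = set()
    for header, lines in _entry_blocks(path):
        if header in seen:
            raise ValueError(f"duplicate record id {header!r} in {path}")
        seen.add(header)
        seq_parts, struct_parts = [], []
        for line in lines:
            # Structure lines contain only ().- ; a line of pure '-' after
            # structure has begun is treated as structure continuation.
            if _STRUCT_RE.match(line) and (set(line) != {"-"} or struct_parts):
                struct_parts.append(line)
            elif struct_parts:
                raise ValueError(
                    f"{path}: record {header!r}: sequence line after structure block"
                )
            else:
                seq_parts.append(line)
        raw_seq = "".join(seq_parts)
        struct = "".join(struct_parts)
        if not raw_seq:
            raise ValueError(f"{path}: record {header!r}: empty sequence")
        if len(struct) != len(raw_seq):
            raise ValueError(
                f"{path}: record {header!r}: sequence length {len(raw_seq)} != "
                f"structure length {len(struct)}"
            )
        for off, (a, b) in enumerate(zip(raw_seq, struct)):
            if (a == "-") != (b == "-"):
                raise ValueError(
                    f"{path}: record {header!r}: gap mismatch at offset {off}"
                )
        validate_dotbracket(struct, allow_gaps=True)
        records.append(Record.from_raw(header, raw_seq, structure=struct))
    return records


def write_xfasta(records: Iterable[Record], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.structure is None:
                raise ValueError(f"record {rec.id!r} has no structure")
            fh.write(f">{rec.id}\n")
            s, db = rec.output_seq, rec.structure
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
            for i in range(0, len(db), width):
                fh.write(db[i : i + width] + "\n")


_VIENNA_ENERGY_RE = re.compile(r"^([().\-]+)(?:\s+\(\s*(-?\d+(?:\.\d+)?)\s*\))?$")


def read_vienna(path) -> list[Record]:
    """Read Vienna format (header / sequence / dot-bracket [energy])."""
    records: list[Record] = []
    seen: set[str] = set()
    for header, lines in _entry_blocks(path):
        if header in seen:
            raise ValueError(f"duplicate record id {header!r} in {path}")
        seen.add(header)
        if len(lines) < 2:
            raise ValueError(f"{path}: record {header!r}: expected 2 body lines")
        raw_seq = lines[0]
        m = _VIENNA_ENERGY_RE.match(" ".join(lines[1:]))
        if not m:
            raise ValueError(f"{path}: record {header!r}: malformed structure line")
        struct, energy = m.group(1), m.group(2)
        if len(struct) != len(raw_seq):
            raise ValueError(
                f"{path}: record {header!r}: sequence length {len(raw_seq)} != "
                f"structure length {len(struct)}"
            )
        records.append(
            Record.from_raw(
                header,
                raw_seq,
                structure=struct,
                energy=float(energy) if energy is not None else None,
            )
        )
    return records


def write_vienna(records: Iterable[Record], path) -> None:
    """Write 3-line Vienna blocks, with the MFE in kcal/mol when known."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.structure is None:
                raise ValueError(f"record {rec.id!r} has no structure")
            fh.write(f">{rec.id}\n{rec.output_seq}\n")
            if rec.energy is not None:
                fh.write(f"{rec.structure} ({rec.energy:.2f})\n")
            else:
                fh.write(rec.structure + "\n")


def write_newick(tree, path) -> None:
    """Write a phylo tree (its1kit.phylo.Node) with 6-decimal branch lengths."""
    for leaf in tree.leaves():
        if not leaf.label:
            raise ValueError("tree has an unlabeled leaf")
    Path(path).write_text(tree.newick() + "\n")
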