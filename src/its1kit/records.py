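"""Core record type and dot-bracket utilities.

The internal alphabet is RNA (``U``); DNA input is accepted and converted,
with the original T/U convention remembered per record so writers can
round-trip.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

GAP = "-"
RNA_ALPHABET = set("ACGUN")
# IUPAC ambiguity codes are kept verbatim; they never pair and act as
# missing data downstream.
IUPAC_EXTRA = set("RYSWKMBDHV")
VALID_LETTERS = RNA_ALPHABET | IUPAC_EXTRA | {GAP}


class DotBracketError(ValueError):
    """Raised for unbalanced or otherwise invalid dot-bracket strings."""


def normalize_seq(raw: str) -> tuple[str, bool]:
    """Uppercase, strip whitespace and convert T->U.

    Returns the RNA-normalized string and a flag marking whether the input
    used the DNA (T) convention.
    """
    s = "".join(raw.split()).upper()
    had_t = "T" in s
    s = s.replace("T", "U")
    bad = set(s) - VALID_LETTERS
    if bad:
        raise ValueError(f"invalid sequence letters: {sorted(bad)!r}")
    return s, had_t


def validate_dotbracket(db: str, *, allow_gaps: bool = False) -> None:
    """Check that *db* is balanced and nested (pseudoknot-free).

    Raises :class:`DotBracketError` with the offending offset otherwise.
    """
    depth = 0
    for i, c in enumerate(db):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise DotBracketError(f"unmatched ')' at offset {i}")
        elif c == ".":
            continue
        elif c == GAP and allow_gaps:
            continue
        else:
            raise DotBracketError(f"invalid structure character {c!r} at offset {i}")
    if depth != 0:
        raise DotBracketError(f"{depth} unmatched '(' at end of string")


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    """Return the (i, j) base pairs of a gap-free dot-bracket string."""
    validate_dotbracket(db)
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    pairs.sort()
    return pairs


def dotbracket_from_pairs(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def partner_array(db: str) -> list[int]:
    """Partner index per position (-1 for unpaired), gap-free input."""
    partner = [-1] * len(db)
    for i, j in pairs_from_dotbracket(db):
        partner[i] = j
        partner[j] = i
    return partner


@dataclass
class Record:
    """A nucleotide sequence with optional structure and element annotation.

    ``seq`` is RNA-normalized (U); ``dna_input`` remembers whether the source
    used T so writers can round-trip.  ``structure`` is dot-bracket of equal
    length when present.  ``elements`` maps element names (e.g. ``helixI``)
    to 0-based half-open spans.
    """

    id: str
    seq: str
    structure: str | None = None
    dna_input: bool = False
    energy: float | None = None
    elements: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.structure is not None and len(self.structure) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"structure length {len(self.structure)}"
            )
        if self.structure is not None:
            validate_dotbracket(self.structure, allow_gaps=GAP in self.seq)

    @classmethod
    def from_raw(
        cls, rec_id: str, raw_seq: str, structure: str | None = None, **kw
    ) -> "Record":
        seq, had_t = normalize_seq(raw_seq)
        return cls(id=rec_id, seq=seq, structure=structure, dna_input=had_t, **kw)

    @property
    def output_seq(self) -> str:
        """Sequence in the convention of the original input (T restored)."""
        return self.seq.replace("U", "T") if self.dna_input else self.seq

    def ungapped(self) -> "Record":
        if GAP not in self.seq:
            return self
        keep = [i for i, c in enumerate(self.seq) if c != GAP]
        seq = "".join(self.seq[i] for i in keep)
        struct = None
        if self.structure is not None:
            struct = "".join(self.structure[i] for i in keep)
        return replace(self, seq=seq, structure=struct)

    def __len__(self) -> int:
        return len(self.seq)
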