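"""ITS1 delineation between the 18S 3'-terminal and 5.8S 5'-terminal motifs.

The ITS1 span of an rDNA record is the region between the best-scoring 18S
terminal HMM hit and the best-scoring 5.8S terminal HMM hit that pass the
configured E-value cutoff: ``[hit18S.end, hit58S.start)``, excluding both
matched termini.  The short (10 nt) models with E <= 0.1 are the default
working mode; the long (25 nt) models with E <= 0.001 are retained for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phmm import HmmHit, ProfileHMM, build_phmm, viterbi_scan
from .records import Record


@dataclass(frozen=True)
class AnnotationConfig:
    hmm_length_mode: str = "short_10"  # or "long_25"
    evalue_cutoff: float = 0.1  # 0.001 for long_25

    def __post_init__(self) -> None:
        if self.hmm_length_mode not in ("short_10", "long_25"):
            raise ValueError(f"unknown mode {self.hmm_length_mode!r}")
        if not self.evalue_cutoff > 0:
            raise ValueError("evalue_cutoff must be > 0")

    @classmethod
    def for_mode(cls, mode: str) -> "AnnotationConfig":
        return cls(mode, 0.1 if mode == "short_10" else 0.001)


@dataclass
class Its1Annotation:
    target_id: str
    its1_start: int | None
    its1_end: int | None
    hit18S: HmmHit | None
    hit58S: HmmHit | None
    status: str  # full | missing_18S | missing_58S | unannotated

    @property
    def span(self) -> tuple[int, int] | None:
        if self.status != "full":
            return None
        return (self.its1_start, self.its1_end)


def build_terminal_hmm(
    alignment: list[str], side: str, k: int, pseudocount: float = 0.1, name: str = ""
) -> ProfileHMM:
    """Build an HMM from the terminal *k* match columns of an alignment.

    ``side='3prime'`` keeps the last k columns (18S gene terminus);
    ``side='5prime'`` keeps the first k (5.8S gene start).
    """
    if side not in ("3prime", "5prime"):
        raise ValueError("side must be '3prime' or '5prime'")
    trimmed = [r[-k:] if side == "3prime" else r[:k] for r in alignment]
    return build_phmm(trimmed, pseudocount, name=name or f"{side}_{k}")


def _best_hit(
    hmm: ProfileHMM, seq: str, cutoff: float, prefer_right: bool, target_id: str
) -> HmmHit | None:
    hits = [
        h
        for h in viterbi_scan(hmm, seq, min_bits=0.0, target_id=target_id)
        if h.evalue is not None and h.evalue <= cutoff
    ]
    if not hits:
        return None
    best = max(h.bit_score for h in hits)
    tied = [h for h in hits if abs(h.bit_score - best) < 1e-9]
    # 18S terminus borders ITS1 from the left: prefer the rightmost tie;
    # 5.8S terminus borders from the right: prefer the leftmost.
    tied.sort(key=lambda h: h.start, reverse=prefer_right)
    return tied[0]


def annotate_its1(
    record: Record,
    hmm18S: ProfileHMM,
    hmm58S: ProfileHMM,
    config: AnnotationConfig = AnnotationConfig(),
) -> Its1Annotation:
    """Delineate the ITS1 span of one record.

    Statuses encode failure modes; no exception is raised for unannotatable
    records.  Annotation is invariant to input case and T/U convention
    (records are already RNA-normalized).
    """
    seq = record.seq
    h18 = _best_hit(hmm18S, seq, config.evalue_cutoff, prefer_right=True, target_id=record.id)
    h58 = _best_hit(hmm58S, seq, config.evalue_cutoff, prefer_right=False, target_id=record.id)
    if h18 is None and h58 is None:
        return Its1Annotation(record.id, None, None, None, None, "unannotated")
    if h18 is None:
        return Its1Annotation(record.id, None, None, None, h58, "missing_18S")
    if h58 is None:
        return Its1Annotation(record.id, None, None, h18, None, "missing_58S")
    if h58.start <= h18.end:
        return Its1Annotation(record.id, None, None, h18, h58, "unannotated")
    return Its1Annotation(record.id, h18.end, h58.start, h18, h58, "full")


def extract_its1(record: Record, ann: Its1Annotation) -> Record | None:
    if ann.status != "full":
        return None
    return Record(
        id=record.id,
        seq=record.seq[ann.its1_start : ann.its1_end],
        dna_input=record.dna_input,
    )


@dataclass
class AnnotationSummary:
    n_records: int = 0
    n_18S_hits: int = 0
    n_58S_hits: int = 0
    n_full: int = 0
    n_unique_its1: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)


def batch_annotate(
    records: list[Record],
    hmm18S: ProfileHMM,
    hmm58S: ProfileHMM,
    config: AnnotationConfig = AnnotationConfig(),
) -> tuple[list[Its1Annotation], AnnotationSummary]:
    """Annotate a batch and summarize: hit counts, full annotations, and the
    number of unique ITS1 strings (exact identity after T->U normalization).
    """
    anns: list[Its1Annotation] = []
    summary = AnnotationSummary(n_records=len(records))
    unique: set[str] = set()
    for rec in records:
        ann = annotate_its1(rec, hmm18S, hmm58S, config)
        anns.append(ann)
        summary.status_counts[ann.status] = summary.status_counts.get(ann.status, 0) + 1
        if ann.hit18S is not None:
            summary.n_18S_hits += 1
        if ann.hit58S is not None:
            summary.n_58S_hits += 1
        if ann.status == "full":
            summary.n_full += 1
            unique.add(rec.seq[ann.its1_start : ann.its1_end])
    summary.n_unique_its1 = len(unique)
    return anns, summary
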