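"""Motif-guided divide-and-conquer ("helix-wise") folding.

When whole-sequence energy minimization fails to produce the three-helix
common core, the sequence is cut at the conserved motifs that open and
close helix II, the three resulting domains are folded independently, and
the dot-brackets are concatenated.  No pair can cross a cut, so the middle
domain is forced to fold as one self-contained region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fold import (
    DEFAULT_CORE,
    CoreClassification,
    CoreSpec,
    SecondaryStructure,
    classify_core,
    decompose_helices,
    fold_mfe,
)
from .energy import DEFAULT_PARAMS, FoldParams
from .phmm import HmmHit, ProfileHMM, viterbi_scan, evalue

CUT_MODES = ("motif_start_end", "motif_midpoints", "motif_end_start")


class SegmentationError(ValueError):
    """Raised when motif hits cannot segment the sequence."""


@dataclass
class MotifModel:
    """A named motif HMM; motifI and motifII are mandatory for segmentation,
    motifs IIIa/IIIb/IV are optional QC."""

    name: str
    hmm: ProfileHMM


@dataclass
class Segmentation:
    cut1: int
    cut2: int
    L: int

    def __post_init__(self) -> None:
        if not (0 < self.cut1 < self.cut2 < self.L):
            raise SegmentationError(
                f"invalid cuts 0 < {self.cut1} < {self.cut2} < {self.L}"
            )

    @property
    def domains(self) -> list[tuple[int, int]]:
        return [(0, self.cut1), (self.cut1, self.cut2), (self.cut2, self.L)]


def scan_motifs(
    seq: str, motif_models: list[MotifModel], evalue_cutoff: float = 0.001
) -> dict[str, HmmHit]:
    """Best hit per motif with E <= cutoff; motifs without a passing hit are
    absent from the result."""
    out: dict[str, HmmHit] = {}
    for model in motif_models:
        hits = [
            h
            for h in viterbi_scan(model.hmm, seq, min_bits=0.0)
            if h.evalue is not None and h.evalue <= evalue_cutoff
        ]
        if hits:
            out[model.name] = hits[0]  # already best-first
    return out


def segment_by_motifs(
    seq: str, hits: dict[str, HmmHit], cut_mode: str = "motif_start_end"
) -> Segmentation:
    """Cut the sequence into three proposed helix domains.

    Default interpretation: motif I opens helix II and motif II closes it,
    so cut1 = motifI.start and cut2 = motifII.end.  Alternative conventions
    are exposed via *cut_mode*.
    """
    if cut_mode not in CUT_MODES:
        raise ValueError(f"unknown cut mode {cut_mode!r}")
    for name in ("motifI", "motifII"):
        if name not in hits:
            raise SegmentationError(f"{name} not found")
    m1, m2 = hits["motifI"], hits["motifII"]
    if not m1.start < m2.end or m1.end > m2.start:
        raise SegmentationError(
            f"motif hits out of order: motifI [{m1.start},{m1.end}) vs "
            f"motifII [{m2.start},{m2.end})"
        )
    if cut_mode == "motif_start_end":
        cut1, cut2 = m1.start, m2.end
    elif cut_mode == "motif_midpoints":
        cut1, cut2 = (m1.start + m1.end) // 2, (m2.start + m2.end) // 2
    else:  # motif_end_start
        cut1, cut2 = m1.end, m2.start
    return Segmentation(cut1, cut2, len(seq))


def fold_helixwise(
    seq: str,
    motif_models: list[MotifModel],
    fold_params: FoldParams = DEFAULT_PARAMS,
    evalue_cutoff: float = 0.001,
    cut_mode: str = "motif_start_end",
) -> SecondaryStructure:
    """Fold each motif-delimited domain independently and concatenate.

    The result's energy is the sum of the domain energies and no pair
    crosses a cut (asserted).
    """
    hits = scan_motifs(seq, motif_models, evalue_cutoff)
    seg = segment_by_motifs(seq, hits, cut_mode)
    db_parts: list[str] = []
    pairs: list[tuple[int, int]] = []
    energy = 0.0
    for start, end in seg.domains:
        sub = fold_mfe(seq[start:end], fold_params)
        db_parts.append(sub.dotbracket)
        pairs.extend((i + start, j + start) for i, j in sub.pairs)
        energy += sub.energy
    structure = SecondaryStructure(seq, "".join(db_parts), sorted(pairs), energy)
    for i, j in structure.pairs:  # no pair crosses a cut, by construction
        for cut in (seg.cut1, seg.cut2):
            assert not (i < cut <= j), f"pair ({i},{j}) crosses cut {cut}"
    return structure


@dataclass
class PipelineResult:
    structure: SecondaryStructure
    method: str  # direct | helixwise | failed
    classification: CoreClassification


def fold_pipeline(
    seq: str,
    motif_models: list[MotifModel],
    fold_params: FoldParams = DEFAULT_PARAMS,
    core_spec: CoreSpec = DEFAULT_CORE,
    evalue_cutoff: float = 0.001,
    cut_mode: str = "motif_start_end",
) -> PipelineResult:
    """Direct fold first; on core failure attempt the helix-wise rescue.

    Returns method 'direct' or 'helixwise' when the corresponding structure
    passes the common-core classifier, else 'failed' with the
    fewer-violations structure attached (tie resolves to direct).
    """
    direct = fold_mfe(seq, fold_params)
    cls_d = classify_core(decompose_helices(direct), core_spec)
    if cls_d.is_core:
        return PipelineResult(direct, "direct", cls_d)
    try:
        hw = fold_helixwise(seq, motif_models, fold_params, evalue_cutoff, cut_mode)
    except SegmentationError:
        hw = None
    if hw is not None:
        cls_h = classify_core(decompose_helices(hw), core_spec)
        if cls_h.is_core:
            return PipelineResult(hw, "helixwise", cls_h)
        if len(cls_h.violations) < len(cls_d.violations):
            return PipelineResult(hw, "failed", cls_h)
    return PipelineResult(direct, "failed", cls_d)
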