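"""Seeded generators of ITS1-like records with known ground truth.

The generator emulates the three-helix common-core architecture of the
anaerobic-fungal ITS1: short 5' and 3' stem-loops (helices I and III), a
long central stem-loop (helix II) whose closing stem starts with the motif
I consensus and ends with the motif II consensus, unpaired inter-helix
regions around a central ring, optional 10-nt 18S/5.8S flanking termini,
and an overall AT content near 0.79.  Unpaired regions are sampled A-biased
so they rarely pair with anything; stems are sampled GC-reinforced so the
planted hairpins are thermodynamically stable in isolation.  All sampling
is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import encode12
from .energy import PAIR_NAMES
from .records import Record, dotbracket_from_pairs, pairs_from_dotbracket
from .phylo import GTRModel12, Node

# Synthetic constants: the study's real flank/motif sequences are not part
# of this package; these stand-ins are fixed, GC-containing, and easily
# detectable by the bundled HMMs.  All are synthetic, not database-derived.
FLANK_18S = "GGAUCAUUAG"  # synthetic 18S rRNA 3'-terminal 10-mer
FLANK_58S = "AACUCGCAGC"  # synthetic 5.8S rRNA 5'-terminal 10-mer
MOTIF_I = "GCAUAUUCAGUAAUGAGC"  # synthetic 18-mer opening helix II

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


#: synthetic 18-mer closing helix II: pairs with motif I on the stem
MOTIF_II = revcomp(MOTIF_I)


def _variant_rows(consensus: str, n_rows: int, seed: int, mut_rate: float = 0.05) -> list[str]:
    """Small training alignment around a consensus (for HMM construction)."""
    rng = np.random.default_rng(seed)
    letters = list("ACGU")
    rows = []
    for _ in range(n_rows):
        row = list(consensus)
        for i in range(len(row)):
            if rng.random() < mut_rate:
                row[i] = letters[rng.integers(0, 4)]
        rows.append("".join(row))
    return rows


def default_training_alignments(n_rows: int = 8, seed: int = 97) -> dict[str, list[str]]:
    """Training alignments for the bundled synthetic flank/motif HMMs."""
    return {
        "flank18S": _variant_rows(FLANK_18S, n_rows, seed + 1),
        "flank58S": _variant_rows(FLANK_58S, n_rows, seed + 2),
        "motifI": _variant_rows(MOTIF_I, n_rows, seed + 3),
        "motifII": _variant_rows(MOTIF_II, n_rows, seed + 4),
    }


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for the generator.

    Helix spans / inter-run lengths are sampled uniformly from the stated
    ranges; helix I and III lower bounds are raised above the classifier's
    so every planted stem is MFE-stable in isolation.  ``at_target`` is
    the overall A+U fraction aimed for (the observed ITS1 value is 0.79);
    stems are sampled less AT-rich than unpaired regions, mirroring the
    observed element-wise AT pattern.
    """

    helixI_len: tuple[int, int] = (14, 35)
    helixII_len: tuple[int, int] = (115, 201)
    helixIII_len: tuple[int, int] = (14, 23)
    inter1: tuple[int, int] = (15, 28)
    inter2: tuple[int, int] = (10, 29)
    start_len: tuple[int, int] = (2, 8)
    stop_len: tuple[int, int] = (2, 8)
    at_target: float = 0.79
    stem_at: dict = field(
        default_factory=lambda: {"helixI": 0.45, "helixII": 0.87, "helixIII": 0.45}
    )
    unpaired_at: float = 0.95
    unpaired_a_bias: float = 0.93
    gu_fraction: float = 0.08
    flanks: bool = False
    motif_i: str = MOTIF_I
    motif_ii: str = MOTIF_II

    def __post_init__(self) -> None:
        if not (0.0 < self.at_target < 1.0):
            raise ValueError("at_target must be in (0, 1)")


DEFAULT_SYNTH = SynthParams()


def _sample_comp(rng, n: int, at: float, a_bias: float = 0.5) -> str:
    """Sample n bases holding the AT fraction by quota (exact counts, then
    shuffled); a_bias splits the AT mass toward A."""
    if n == 0:
        return ""
    n_at = int(round(n * at))
    n_a = int(round(n_at * a_bias))
    n_u = n_at - n_a
    n_c = (n - n_at) // 2
    n_g = n - n_at - n_c
    letters = ["A"] * n_a + ["U"] * n_u + ["C"] * n_c + ["G"] * n_g
    rng.shuffle(letters)
    return "".join(letters)


def _stem_loop(rng, span: int, at: float, gu: float, prefix: str = "") -> tuple[str, str]:
    """Build a stem-loop of total span nt; returns (sequence, dotbracket).

    The 5' arm starts with *prefix* (motif placement); the 3' arm is its
    reverse complement with a GU-wobble fraction, so the 3' arm ends with
    the reverse complement of the prefix.
    """
    # short stem-loops get a minimal loop so the arm keeps enough stacks to
    # be stable in isolation; long ones draw a loop of 4-8
    if span <= 26:
        loop = 4
    else:
        loop = int(rng.integers(4, 8))
    if (span - loop) % 2 == 1:
        loop += 1
    arm = (span - loop) // 2
    if arm < 2:
        raise ValueError(f"span {span} too short for a stem-loop")
    if len(prefix) > arm:
        raise ValueError(f"motif ({len(prefix)} nt) longer than its host arm ({arm} nt)")
    arm5 = prefix + _sample_comp(rng, arm - len(prefix), at)
    arm3 = list(revcomp(arm5))
    # wobble: flip a fraction of C/A partners to U/G where the 5' base allows
    for k in range(arm):
        i5 = arm - 1 - k  # arm5 position paired with arm3[k]
        if k < len(prefix) or i5 < len(prefix):
            continue  # keep motif-involved pairs exact
        if arm > 15 and rng.random() < gu:
            if arm5[i5] == "G":
                arm3[k] = "U"
            elif arm5[i5] == "U":
                arm3[k] = "G"
    seq = arm5 + _sample_comp(rng, loop, 0.95, a_bias=0.9) + "".join(arm3)
    db = "(" * arm + "." * loop + ")" * arm
    return seq, db


def simulate_its1(
    params: SynthParams = DEFAULT_SYNTH, seed: int = 0, rec_id: str | None = None
) -> Record:
    """Generate one ITS1-like record with ground-truth structure and
    element spans (plus optional 18S/5.8S flanks)."""
    rng = np.random.default_rng(seed)

    def draw(rg: tuple[int, int]) -> int:
        return int(rng.integers(rg[0], rg[1] + 1))

    ua, ub = params.unpaired_at, params.unpaired_a_bias
    start = _sample_comp(rng, draw(params.start_len), 0.95, a_bias=ub)
    stop = _sample_comp(rng, draw(params.stop_len), 0.95, a_bias=ub)
    inter1 = _sample_comp(rng, draw(params.inter1), ua, a_bias=ub)
    inter2 = _sample_comp(rng, draw(params.inter2), ua, a_bias=ub)
    h1_seq, h1_db = _stem_loop(
        rng, draw(params.helixI_len), params.stem_at["helixI"], params.gu_fraction
    )
    h2_seq, h2_db = _stem_loop(
        rng,
        draw(params.helixII_len),
        params.stem_at["helixII"],
        params.gu_fraction,
        prefix=params.motif_i,
    )
    if not h2_seq.endswith(params.motif_ii):
        raise AssertionError("motif II must close helix II")
    h3_seq, h3_db = _stem_loop(
        rng, draw(params.helixIII_len), params.stem_at["helixIII"], params.gu_fraction
    )

    parts = [
        ("start", start, "." * len(start)),
        ("helixI", h1_seq, h1_db),
        ("inter1", inter1, "." * len(inter1)),
        ("helixII", h2_seq, h2_db),
        ("inter2", inter2, "." * len(inter2)),
        ("helixIII", h3_seq, h3_db),
        ("stop", stop, "." * len(stop)),
    ]
    if params.flanks:
        parts = [("flank18S", FLANK_18S, "." * 10)] + parts + [("flank58S", FLANK_58S, "." * 10)]
    seq = "".join(p[1] for p in parts)
    db = "".join(p[2] for p in parts)
    elements: dict[str, tuple[int, int]] = {}
    off = 0
    for name, s, _ in parts:
        elements[name] = (off, off + len(s))
        off += len(s)
    rid = rec_id or f"synth{seed}"
    return Record(id=rid, seq=seq, structure=db, elements=elements)


def its1_span(record: Record) -> tuple[int, int]:
    """Ground-truth ITS1 span of a generated record (whole record unless
    flanked)."""
    if record.elements and "flank18S" in record.elements:
        return (record.elements["flank18S"][1], record.elements["flank58S"][0])
    return (0, len(record.seq))


def mutate_with_cbcs(record: Record, k: int, seed: int = 0) -> Record:
    """Derive a record with exactly k planted full CBCs.

    k distinct ground-truth pairs are substituted with a different legal
    pair in which both partners change; the structure is untouched.
    """
    if record.structure is None:
        raise ValueError("record has no ground-truth structure")
    pairs = pairs_from_dotbracket(record.structure)
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds available pairs ({len(pairs)})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=k, replace=False)
    seq = list(record.seq)
    for idx in chosen:
        i, j = pairs[idx]
        a, b = seq[i], seq[j]
        options = [p for p in PAIR_NAMES if p[0] != a and p[1] != b]
        new = options[rng.integers(0, len(options))]
        seq[i], seq[j] = new[0], new[1]
    return replace(record, id=record.id + f"_cbc{k}", seq="".join(seq))


# ---------------------------------------------------------------------------
# clade simulation under the 12-state model


def random_tree(n_taxa: int, depth: float, seed: int = 0) -> Node:
    """Random bifurcating tree over taxa t0..t{n-1} with uniform branch
    lengths in (0.05*depth, depth] (all zero when depth == 0)."""
    rng = np.random.default_rng(seed)

    def blen() -> float:
        return float(rng.uniform(0.05 * depth, depth)) if depth > 0 else 0.0

    def build(labels: list[str]) -> Node:
        if len(labels) == 1:
            return Node(label=labels[0], length=blen())
        cut = int(rng.integers(1, len(labels)))
        return Node(length=blen(), children=[build(labels[:cut]), build(labels[cut:])])

    labels = [f"t{i}" for i in range(n_taxa)]
    root = build(labels)
    root.length = 0.0
    return root


def simulate_alignment(
    tree: Node, model: GTRModel12, n_sites: int, seed: int = 0
) -> dict[str, np.ndarray]:
    """Evolve free 12-state sequences along a tree; returns leaf rows."""
    rng = np.random.default_rng(seed)
    root_states = rng.choice(12, size=n_sites, p=model.pi)
    out: dict[str, np.ndarray] = {}

    def walk(node: Node, states: np.ndarray):
        if node.length > 0:
            P = model.transition_matrix(node.length)
            new = np.empty_like(states)
            for s in range(12):
                idx = states == s
                if np.any(idx):
                    new[idx] = rng.choice(12, size=int(idx.sum()), p=P[s] / P[s].sum())
            states = new
        if node.is_leaf():
            out[node.label] = states.copy()
        for ch in node.children:
            walk(ch, states)

    walk(tree, root_states)
    return out


def simulate_clade(
    n_taxa: int,
    tree_depth: float,
    model: GTRModel12,
    seed: int = 0,
    params: SynthParams = DEFAULT_SYNTH,
) -> tuple[list[Record], Node]:
    """Evolve an ITS1-like root record along a random tree.

    Substitution runs under the 12-state model restricted per site to the
    four states compatible with the root's structural state (the structure
    is held fixed), so every leaf decodes to a valid record sharing the
    root's dot-bracket.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    tree = random_tree(n_taxa, tree_depth, seed=int(rng.integers(2**31)))
    root = simulate_its1(params, seed=int(rng.integers(2**31)))
    code = encode12(root.seq, root.structure)
    states = code.codes.astype(np.int64)
    struct_state = states % 3
    records: list[Record] = []

    def walk(node: Node, cur: np.ndarray):
        if node.length > 0:
            P = model.transition_matrix(node.length)
            new = cur.copy()
            for site in range(len(cur)):
                allowed = np.arange(struct_state[site], 12, 3)
                probs = P[cur[site], allowed]
                new[site] = allowed[rng.choice(4, p=probs / probs.sum())]
            cur = new
        if node.is_leaf():
            seq = "".join("ACGU"[c // 3] for c in cur)
            records.append(Record(id=node.label, seq=seq, structure=root.structure))
        for ch in node.children:
            walk(ch, cur)

    walk(tree, states)
    return records, tree
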