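"""Sequence-structure phylogenetics: 12-state GTR distances, Neighbor
Joining, bootstrap support and iterative Profile Neighbor Joining.

Distances are maximum-likelihood under a general time reversible model over
the 12-letter sequence-structure alphabet, with pairwise deletion of
gapped/ambiguous columns.  Trees come from Saitou-Nei Neighbor Joining;
support values from column-resampling bootstrap.  Profile Neighbor Joining
iteratively condenses well-supported clades into position-wise 12-state
frequency profiles and re-joins until no new profile forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .alphabet import GAP_CODE, N_SYMBOLS

MAX_DISTANCE = 10.0


# ---------------------------------------------------------------------------
# trees


class Node:
    """A rooted view of an (in general unrooted) phylogenetic tree."""

    __slots__ = ("label", "length", "support", "children")

    def __init__(self, label: str = "", length: float = 0.0, children=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[Node] = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out: list[Node] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(l.label for l in self.leaves())

    def newick(self) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf():
                body = node.label
            else:
                inner = ",".join(fmt(ch, False) for ch in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){sup}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self, True) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side NOT containing
        the lexicographically smallest leaf label."""
        all_leaves = self.leaf_labels()
        anchor = min(all_leaves)
        splits: set[frozenset] = set()

        def walk(node: Node):
            for ch in node.children:
                side = ch.leaf_labels()
                if anchor in side:
                    side = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(side)
                walk(ch)

        walk(self)
        return splits

    def pairwise_distances(self) -> dict[tuple[str, str], float]:
        """Path-length distances between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf():
                return {node.label: 0.0}
            acc: dict[str, float] = {}
            for ch in node.children:
                below = {k: v + ch.length for k, v in walk(ch).items()}
                for a, da in acc.items():
                    for b, db in below.items():
                        key = (a, b) if a < b else (b, a)
                        dists[key] = da + db
                acc.update(below)
            return acc

        walk(self)
        return dists


# ---------------------------------------------------------------------------
# GTR model over 12 states


@dataclass
class GTRModel12:
    """Time-reversible 12-state substitution model.

    ``pi``: stationary frequencies; ``exchangeabilities``: symmetric,
    zero-diagonal; ``Q`` is scaled to one expected substitution per unit
    time and satisfies detailed balance.
    """

    pi: np.ndarray
    exchangeabilities: np.ndarray
    Q: np.ndarray = field(init=False)
    _eig: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        R = np.asarray(self.exchangeabilities, dtype=float)
        if not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("pi must sum to 1")
        if not np.allclose(R, R.T):
            raise ValueError("exchangeabilities must be symmetric")
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        if rate <= 0:
            raise ValueError("degenerate model: zero substitution rate")
        Q /= rate
        self.pi = pi
        self.exchangeabilities = R
        self.Q = Q
        # reversible: symmetrize with pi^{1/2} and eigendecompose once
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eig = (w, U, sq)

    def transition_matrix(self, t: float) -> np.ndarray:
        w, U, sq = self._eig
        P = (U * np.exp(w * t)) @ U.T
        P = (P / sq[:, None]) * sq[None, :]
        return np.clip(P, 1e-300, None)


def uniform_gtr12() -> GTRModel12:
    """Equal-rates 12-state model (the JC-like special case)."""
    pi = np.full(N_SYMBOLS, 1.0 / N_SYMBOLS)
    R = np.ones((N_SYMBOLS, N_SYMBOLS))
    np.fill_diagonal(R, 0.0)
    return GTRModel12(pi, R)


def random_gtr12(seed: int) -> GTRModel12:
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.full(N_SYMBOLS, 5.0))
    R = rng.gamma(2.0, 1.0, size=(N_SYMBOLS, N_SYMBOLS))
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 0.0)
    return GTRModel12(pi, R)


def estimate_gtr(rows: list[np.ndarray], pseudocount: float = 0.5) -> GTRModel12:
    """Estimate a GTRModel12 from gapped alignment rows (int codes, -1 gap).

    pi is the pseudocount-smoothed symbol frequency; exchangeabilities come
    from the symmetrized pairwise substitution count matrix over all row
    pairs (pairwise deletion of gapped columns).
    """
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    R_ = np.stack(rows)
    valid = R_ >= 0
    counts = np.bincount(R_[valid], minlength=N_SYMBOLS).astype(float)
    if np.count_nonzero(counts) <= 1:
        raise ValueError("degenerate alignment: a single distinct symbol")
    pi = (counts + pseudocount) / (counts.sum() + N_SYMBOLS * pseudocount)
    C = np.zeros((N_SYMBOLS, N_SYMBOLS))
    nrows = len(rows)
    for i in range(nrows):
        for j in range(i + 1, nrows):
            both = valid[i] & valid[j]
            a, b = R_[i][both], R_[j][both]
            np.add.at(C, (a, b), 1.0)
    C = C + C.T + 2.0 * pseudocount
    np.fill_diagonal(C, 0.0)
    return GTRModel12(pi, C)


def _pair_counts(row_i: np.ndarray, row_j: np.ndarray) -> np.ndarray:
    both = (row_i >= 0) & (row_j >= 0)
    if not np.any(both):
        raise ValueError("no shared ungapped columns")
    C = np.zeros((N_SYMBOLS, N_SYMBOLS))
    np.add.at(C, (row_i[both], row_j[both]), 1.0)
    return C


def _ml_distance(C: np.ndarray, model: GTRModel12) -> float:
    total = C.sum()
    if total <= 0:
        raise ValueError("no shared ungapped columns")
    if C.sum() == np.trace(C):
        return 0.0
    logpi = np.log(model.pi)

    def nll(t: float) -> float:
        P = model.transition_matrix(t)
        return -float((C * (logpi[:, None] + np.log(P))).sum())

    res = minimize_scalar(
        nll, bounds=(1e-8, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-10},
    )
    d = float(res.x)
    if d >= MAX_DISTANCE - 1e-6:
        return MAX_DISTANCE
    return d


def gtr_distance(row_i: np.ndarray, row_j: np.ndarray, model: GTRModel12) -> float:
    """ML sequence-structure distance between two gapped rows.

    Maximizes sum_sites log(pi_a * P(a->b | t)) by bounded scalar
    optimization; saturates at MAX_DISTANCE.
    """
    return _ml_distance(_pair_counts(row_i, row_j), model)


def jc12_distance(p_mismatch: float) -> float:
    """Closed-form equal-rates 12-state distance.

    jc12(p) = -(11/12) ln(1 - (12/11) p); saturates at MAX_DISTANCE for
    p >= 11/12.
    """
    if p_mismatch < 0:
        raise ValueError("mismatch fraction must be >= 0")
    if p_mismatch >= 11.0 / 12.0:
        return MAX_DISTANCE
    return -(11.0 / 12.0) * math.log(1.0 - (12.0 / 11.0) * p_mismatch)


def distance_matrix(rows: list[np.ndarray], model: GTRModel12) -> np.ndarray:
    k = len(rows)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = gtr_distance(rows[i], rows[j], model)
    return D


# ---------------------------------------------------------------------------
# Neighbor Joining


def _nj_nodes(D: np.ndarray, nodes: list[Node]) -> Node:
    """Saitou-Nei NJ over pre-built leaf nodes; ties break on the smallest
    (i, j) active-index pair.  Negative branch lengths are clamped to zero
    with the deficit moved to the sister edge."""
    D = D.astype(float).copy()
    active = list(range(len(nodes)))
    nodes = list(nodes)
    if len(nodes) == 1:
        return nodes[0]
    if len(nodes) == 2:
        d = D[0, 1]
        nodes[0].length = d / 2.0
        nodes[1].length = d / 2.0
        return Node(children=[nodes[0], nodes[1]])
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        best = (np.inf, None)
        for ai in range(n):
            for aj in range(ai + 1, n):
                q = Qm[ai, aj]
                if q < best[0] - 1e-12:
                    best = (q, (ai, aj))
        ai, aj = best[1]
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        # clamp-and-transfer
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            if li < 0:
                li = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        # distances to the new node
        newrow = np.zeros(D.shape[0] + 1)
        for ak in range(n):
            k = active[ak]
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join the last three on the unrooted "root"
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    lens = [li, lj, lk]
    for idx in range(3):
        if lens[idx] < 0:
            # move deficit to the smaller of the two sister edges
            other = min((o for o in range(3) if o != idx), key=lambda o: lens[o])
            lens[other] += lens[idx]
            lens[idx] = 0.0
    nodes[i].length, nodes[j].length, nodes[k].length = lens
    return Node(children=[nodes[i], nodes[j], nodes[k]])


def nj(D: np.ndarray, labels: list[str]) -> Node:
    """Neighbor Joining on a symmetric, zero-diagonal distance matrix."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or D.shape[0] != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    return _nj_nodes(D, [Node(label=l) for l in labels])


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    rows: list[np.ndarray],
    labels: list[str],
    model: GTRModel12,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[Node, dict[frozenset, float]]:
    """Column-resampling bootstrap of the distance+NJ tree.

    Returns the full-data tree with supports attached (percent of
    replicates containing each original bipartition).
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    tree = nj(distance_matrix(rows, model), labels)
    splits = tree.bipartitions()
    hits = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = len(rows[0])
    mat = np.stack(rows)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = [mat[i][cols] for i in range(len(rows))]
        try:
            rep_tree = nj(distance_matrix(rep_rows, model), labels)
        except ValueError:
            continue
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    supports = {s: 100.0 * h / n_replicates for s, h in hits.items()}
    _annotate_supports(tree, supports)
    return tree, supports


def support_class(value: float | None) -> str:
    """Figure-style support classes: open circle 50-90, closed > 90."""
    if value is None or value < 50:
        return "none"
    return "closed" if value > 90 else "open"


def _annotate_supports(tree: Node, supports: dict[frozenset, float]) -> None:
    all_leaves = tree.leaf_labels()
    anchor = min(all_leaves)

    def walk(node: Node):
        for ch in node.children:
            if not ch.is_leaf():
                side = ch.leaf_labels()
                if anchor in side:
                    side = all_leaves - side
                if side in supports:
                    ch.support = supports[side]
            walk(ch)

    walk(tree)


# ---------------------------------------------------------------------------
# Profile Neighbor Joining


@dataclass
class _Profile:
    name: str
    freqs: np.ndarray  # (ncol, 12); row mass 0 marks a gap site
    weight: float
    members: list[str]
    subtree: Node | None  # condensed clade structure; None for a single leaf


def _profile_distance(p1: _Profile, p2: _Profile, model: GTRModel12) -> float:
    mass1 = p1.freqs.sum(axis=1)
    mass2 = p2.freqs.sum(axis=1)
    both = (mass1 > 0) & (mass2 > 0)
    if not np.any(both):
        raise ValueError("profiles share no ungapped columns")
    C = p1.freqs[both].T @ p2.freqs[both]
    return _ml_distance(C, model)


def _profile_dm(profiles: list[_Profile], model: GTRModel12) -> np.ndarray:
    k = len(profiles)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            D[i, j] = D[j, i] = _profile_distance(profiles[i], profiles[j], model)
    return D


@dataclass
class PNJResult:
    tree: Node
    supports: dict[frozenset, float]
    iterations: int
    profiles: list[list[list[str]]]  # per iteration: member lists of condensed profiles


def _row_to_freqs(row: np.ndarray) -> np.ndarray:
    f = np.zeros((len(row), N_SYMBOLS))
    idx = row >= 0
    f[np.where(idx)[0], row[idx]] = 1.0
    return f


def profile_nj(
    rows: list[np.ndarray],
    labels: list[str],
    model: GTRModel12,
    n_replicates: int = 100,
    support_threshold: float = 70.0,
    max_iter: int = 20,
    seed: int = 0,
) -> PNJResult:
    """Iterative Profile Neighbor Joining.

    Each iteration runs distance+NJ with bootstrap; clades with support >=
    threshold are condensed into position-wise 12-state frequency profiles
    (weighted means of their members), and distances between profiles are
    expected-count GTR distances.  Iteration stops when no new profile
    forms or max_iter is reached; the final tree expands profiles back to
    the original leaves.
    """
    profiles = [
        _Profile(name=l, freqs=_row_to_freqs(r), weight=1.0, members=[l], subtree=None)
        for r, l in zip(rows, labels)
    ]
    rng = np.random.default_rng(seed)
    all_supports: dict[frozenset, float] = {}
    condensed_per_iter: list[list[list[str]]] = []
    iterations = 0
    tree: Node | None = None
    prof_trees: dict[str, Node] = {}

    while iterations < max_iter:
        iterations += 1
        k = len(profiles)
        names = [p.name for p in profiles]
        D = _profile_dm(profiles, model)
        base_nodes = [Node(label=n) for n in names]
        tree = _nj_nodes(D, base_nodes)
        # bootstrap over columns
        splits = tree.bipartitions() if k >= 4 else set()
        hits = {s: 0 for s in splits}
        ncol = profiles[0].freqs.shape[0]
        if splits:
            for _ in range(n_replicates):
                cols = rng.integers(0, ncol, size=ncol)
                rep = [
                    _Profile(p.name, p.freqs[cols], p.weight, p.members, None)
                    for p in profiles
                ]
                try:
                    rep_tree = _nj_nodes(_profile_dm(rep, model), [Node(label=n) for n in names])
                except ValueError:
                    continue
                rep_splits = rep_tree.bipartitions()
                for s in splits:
                    if s in rep_splits:
                        hits[s] += 1
        supports = {s: 100.0 * h / n_replicates for s, h in hits.items()}
        _annotate_supports(tree, supports)
        # record supports in terms of original leaf labels
        name_to_members = {p.name: p.members for p in profiles}
        for s, v in supports.items():
            expanded = frozenset(m for nm in s for m in name_to_members[nm])
            all_supports[expanded] = v
        # find condensable clades among rooted child subtrees: each split's
        # child side is a clade in the rooted view; require support >=
        # threshold and >= 2 member profiles, take maximal disjoint clades
        all_names = frozenset(names)
        anchor_names = min(all_names)
        candidates: list[tuple[frozenset, Node]] = []

        def collect(node: Node):
            for ch in node.children:
                if not ch.is_leaf():
                    side = ch.leaf_labels()
                    canon = (all_names - side) if anchor_names in side else side
                    v = supports.get(canon)
                    if v is not None and v >= support_threshold and len(side) >= 2:
                        candidates.append((side, ch))
                collect(ch)

        collect(tree)
        candidates.sort(key=lambda t: (-len(t[0]), sorted(t[0])))
        chosen: list[tuple[frozenset, Node]] = []
        used: set[str] = set()
        for side, node_ in candidates:
            if not (side & used):
                chosen.append((side, node_))
                used |= side
        if not chosen:
            condensed_per_iter.append([])
            break
        # condense
        by_name = {p.name: p for p in profiles}
        iter_record: list[list[str]] = []
        new_profiles = [p for p in profiles if p.name not in used]
        for ci, (side, clade_node) in enumerate(chosen):
            members_prof = [by_name[nm] for nm in sorted(side)]
            w = sum(p.weight for p in members_prof)
            freqs = sum(p.weight * p.freqs for p in members_prof) / w
            members = [m for p in members_prof for m in p.members]
            pname = f"profile_{iterations}_{ci}"
            new_profiles.append(_Profile(pname, freqs, w, members, clade_node))
            prof_trees[pname] = clade_node
            iter_record.append(sorted(members))
        condensed_per_iter.append(iter_record)
        profiles = new_profiles
        if len(profiles) < 2:
            break

    assert tree is not None

    # expand condensed profiles back to leaves
    def expand(node: Node) -> Node:
        if node.is_leaf() and node.label in prof_trees:
            sub = prof_trees[node.label]
            replacement = Node(
                label="", length=node.length, support=node.support,
                children=[expand(ch) for ch in sub.children],
            )
            if not replacement.children:  # clade node was itself a leaf
                replacement.label = sub.label
            return replacement
        out = Node(label=node.label, length=node.length, support=node.support)
        out.children = [expand(ch) for ch in node.children]
        return out

    final = expand(tree)
    return PNJResult(final, all_supports, iterations, condensed_per_iter)


def edge_table(tree: Node) -> list[dict]:
    """TSV-friendly edge rows: id, support, length, figure class."""
    rows: list[dict] = []
    counter = [0]

    def walk(node: Node):
        for ch in node.children:
            counter[0] += 1
            rows.append(
                {
                    "edge_id": counter[0],
                    "child": ch.label or "internal",
                    "length": ch.length,
                    "support": ch.support,
                    "class": support_class(ch.support),
                }
            )
            walk(ch)

    walk(tree)
    return rows
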