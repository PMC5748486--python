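"""Maximum-compatibility rooted sample phylogenies from binary presence data.

Each mutation is a binary character over the samples.  A mutation is
*compatible* with a rooted tree when some clade contains all its carriers and
excludes all its explicit non-carriers (missing cells constrain nothing); the
tree score is the number of compatible mutations and the best tree is the
topology maximising it.  Every compatible mutation is assigned to the
incoming edge of the smallest such clade, so branch lengths equal the number
of mutations supporting each separation; the edge above the root is the
trunk, carrying the mutations of the ancestral clone.  Mutations compatible
with no clade of the chosen tree (homoplasies) support no branch and are
reported separately.

Search is exhaustive over all (2n-3)!! rooted binary leaf-labelled topologies
up to a configurable limit (default 9 leaves), otherwise hill climbing over
subtree-prune-regraft and rerooting moves from an average-linkage join tree,
with random restarts.  Ties are broken by lexicographically smallest
canonical newick.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .matrix import ABSENT, MISSING, PRESENT, PresenceMatrix

__all__ = [
    "PhyloTree",
    "enumerate_rooted_trees",
    "count_rooted_trees",
    "score_tree",
    "best_tree",
    "to_newick",
    "canonicalize",
    "tree_leaves",
    "nni_neighbors",
    "spr_neighbors",
    "reroot_candidates",
    "random_topology",
]

logger = logging.getLogger(__name__)

#: A rooted binary topology: a leaf label or a pair of subtrees.
TreeNode = Union[str, tuple]

DEFAULT_EXHAUSTIVE_LIMIT = 9


# ---------------------------------------------------------------------------
# Topology basics
# ---------------------------------------------------------------------------


def tree_leaves(tree: TreeNode) -> tuple[str, ...]:
    """Sorted leaf labels of a topology."""
    out: list[str] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        if isinstance(node, str):
            out.append(node)
        else:
            stack.extend(node)
    return tuple(sorted(out))


def canonicalize(tree: TreeNode) -> TreeNode:
    """Order children by smallest leaf label, recursively."""

    def rec(node: TreeNode) -> tuple[TreeNode, str]:
        if isinstance(node, str):
            return node, node
        (left, lmin), (right, rmin) = rec(node[0]), rec(node[1])
        if rmin < lmin:
            left, right = right, left
            lmin, rmin = rmin, lmin
        return (left, right), lmin

    return rec(tree)[0]


def count_rooted_trees(n_leaves: int) -> int:
    """(2n-3)!! rooted binary leaf-labelled topologies on n leaves."""
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    count = 1
    for k in range(3, 2 * n_leaves - 2, 2):
        count *= k
    return count


def _graft_everywhere(tree: TreeNode, leaf: str) -> Iterator[TreeNode]:
    """All topologies obtained by attaching ``leaf`` onto any edge of ``tree``
    (including the edge above the root)."""
    yield (tree, leaf)
    if not isinstance(tree, str):
        left, right = tree
        for sub in _graft_everywhere(left, leaf):
            yield (sub, right)
        for sub in _graft_everywhere(right, leaf):
            yield (left, sub)


def enumerate_rooted_trees(
    leaves: Sequence[str], limit: int = DEFAULT_EXHAUSTIVE_LIMIT
) -> Iterator[TreeNode]:
    """Yield every rooted binary leaf-labelled topology exactly once.

    Raises above ``limit`` leaves, directing callers to the heuristic search.
    """
    labels = sorted(leaves)
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels must be unique")
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves to enumerate topologies")
    if len(labels) > limit:
        raise ValueError(
            f"{len(labels)} leaves exceed the exhaustive limit {limit} "
            f"({count_rooted_trees(len(labels))} topologies); use hill_climb"
        )

    def gen(k: int) -> Iterator[TreeNode]:
        if k == 1:
            yield labels[0]
            return
        for t in gen(k - 1):
            yield from _graft_everywhere(t, labels[k - 1])

    return gen(len(labels))


def random_topology(leaves: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Uniform random rooted binary topology via sequential random grafting."""
    labels = sorted(leaves)
    tree: TreeNode = labels[0]
    for leaf in labels[1:]:
        options = list(_graft_everywhere(tree, leaf))
        tree = options[int(rng.integers(0, len(options)))]
    return tree


def reroot_candidates(tree: TreeNode) -> list[TreeNode]:
    """Every rooting of the tree's unrooted topology (root on each edge).

    Rooted compatibility scores depend on root placement, which
    nearest-neighbour interchange cannot move, so the hill climb considers
    rerootings as additional neighbours.
    """
    if isinstance(tree, str):
        return [tree]
    out: set[TreeNode] = set()

    def walk(node: TreeNode, rest: TreeNode) -> None:
        out.add(canonicalize((node, rest)))
        if not isinstance(node, str):
            a, b = node
            walk(a, (b, rest))
            walk(b, (a, rest))

    left, right = tree
    walk(left, right)
    walk(right, left)
    return list(out)


def spr_neighbors(tree: TreeNode) -> list[TreeNode]:
    """All topologies one subtree-prune-and-regraft move away.

    Every subtree (leaf or internal) is detached and reattached onto every
    edge of the remainder, including above its root.  This neighbourhood
    contains all nearest-neighbour interchanges and escapes the plateaus
    that trap plain NNI ascent on conflicting character matrices.
    """
    if isinstance(tree, str):
        return []
    pruned: list[tuple[TreeNode, TreeNode]] = []

    def prune(node: TreeNode, rebuild) -> None:
        if isinstance(node, str):
            return
        a, b = node
        for sub, rem in ((a, b), (b, a)):
            pruned.append((sub, rebuild(rem)))
            prune(sub, lambda x, rem=rem, rb=rebuild: rb((x, rem)))

    prune(tree, lambda x: x)
    self_key = canonicalize(tree)
    out: set[TreeNode] = set()
    for sub, remainder in pruned:
        for regrafted in _graft_everywhere(remainder, sub):
            candidate = canonicalize(regrafted)
            if candidate != self_key:
                out.add(candidate)
    return list(out)


def nni_neighbors(tree: TreeNode) -> list[TreeNode]:
    """All topologies one nearest-neighbour interchange away."""
    if isinstance(tree, str):
        return []
    left, right = tree
    out: list[TreeNode] = []
    if not isinstance(left, tuple) and not isinstance(right, tuple):
        return []
    if isinstance(left, tuple):
        a, b = left
        out.append(((right, b), a))
        out.append(((a, right), b))
    if isinstance(right, tuple):
        a, b = right
        out.append((a, (left, b)))
        out.append((b, (left, a)))
    out.extend((sub, right) for sub in nni_neighbors(left))
    out.extend((left, sub) for sub in nni_neighbors(right))
    return out


# ---------------------------------------------------------------------------
# Characters and scoring
# ---------------------------------------------------------------------------


def _extract_patterns(
    presence: PresenceMatrix,
) -> tuple[list[str], list[tuple[int, int, str]]]:
    """Leaf order plus (carrier_mask, absent_mask, id) per mutation."""
    leaves = sorted(presence.samples)
    if len(leaves) < 2:
        raise ValueError("phylogeny needs at least 2 samples")
    idx = {s: i for i, s in enumerate(leaves)}
    states = presence.states
    if len(states):
        informative = (states != MISSING).any(axis=0)
        for sample in presence.samples:
            if not informative[sample]:
                raise ValueError(f"sample {sample!r} is missing in every mutation")
    patterns: list[tuple[int, int, str]] = []
    for mid in states.index:
        row = states.loc[mid]
        c = a = 0
        for s in leaves:
            if row[s] == PRESENT:
                c |= 1 << idx[s]
            elif row[s] == ABSENT:
                a |= 1 << idx[s]
        if c == 0:
            warnings.warn(f"mutation {mid!r} has no carriers; skipped in tree scoring")
            continue
        patterns.append((c, a, mid))
    return leaves, patterns


def _node_masks(tree: TreeNode, idx: dict[str, int]) -> dict[TreeNode, int]:
    """Leaf-set bitmask of every node (post-order, iterative)."""
    masks: dict[TreeNode, int] = {}
    stack: list[tuple[TreeNode, bool]] = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if isinstance(node, str):
            masks[node] = 1 << idx[node]
        elif expanded:
            masks[node] = masks[node[0]] | masks[node[1]]
        else:
            stack.append((node, True))
            stack.append((node[0], False))
            stack.append((node[1], False))
    return masks


def _internal_masks(tree: TreeNode, idx: dict[str, int]) -> list[int]:
    """Masks of non-root internal nodes (the n-2 nontrivial clades)."""
    masks = _node_masks(tree, idx)
    return [m for node, m in masks.items() if isinstance(node, tuple) and node is not tree]


def _score_topology(
    tree: TreeNode,
    patterns: Sequence[tuple[int, int, str]],
    idx: dict[str, int],
    full: int,
) -> int:
    """Compatibility score of one topology (no edge assignment)."""
    internals = _internal_masks(tree, idx)
    score = 0
    for c, a, _ in patterns:
        if c & (c - 1) == 0 or a == 0:  # singleton carrier or trunk-compatible
            score += 1
            continue
        for m in internals:
            if (m & c) == c and (m & a) == 0:
                score += 1
                break
    return score


def score_tree(
    tree: TreeNode, presence: PresenceMatrix
) -> tuple[int, dict[frozenset, list[str]], list[str]]:
    """Score a topology and assign each compatible mutation to an edge.

    Returns (score, {clade leaf-set -> mutation ids}, homoplastic ids).  Each
    compatible mutation goes to the smallest clade containing its carriers
    and excluding its explicit non-carriers; the full leaf set is the trunk.
    """
    leaves, patterns = _extract_patterns(presence)
    if set(tree_leaves(tree)) != set(leaves):
        raise ValueError("tree leaf set does not match presence matrix samples")
    idx = {s: i for i, s in enumerate(leaves)}
    masks = _node_masks(tree, idx)
    # all 2n-1 clades, smallest first
    clade_masks = sorted(set(masks.values()), key=lambda m: bin(m).count("1"))
    mask_to_set = {
        m: frozenset(s for s in leaves if m >> idx[s] & 1) for m in clade_masks
    }
    assignment: dict[frozenset, list[str]] = {mask_to_set[m]: [] for m in clade_masks}
    homoplasies: list[str] = []
    score = 0
    for c, a, mid in patterns:
        for m in clade_masks:
            if (m & c) == c and (m & a) == 0:
                assignment[mask_to_set[m]].append(mid)
                score += 1
                break
        else:
            homoplasies.append(mid)
    return score, assignment, homoplasies


# ---------------------------------------------------------------------------
# Exhaustive search (vectorised over cached topology clades)
# ---------------------------------------------------------------------------

_MASK_CACHE: dict[int, np.ndarray] = {}


def _topology_masks(n: int) -> np.ndarray:
    """(T, n-2) array of internal-clade bitmasks for all topologies on n
    generic leaves in sorted index order.  Cached per n."""
    if n in _MASK_CACHE:
        return _MASK_CACHE[n]
    labels = [f"{i:02d}" for i in range(n)]
    idx = {s: i for i, s in enumerate(labels)}
    rows = np.empty((count_rooted_trees(n), max(n - 2, 0)), dtype=np.uint32)
    for t_i, tree in enumerate(enumerate_rooted_trees(labels, limit=max(n, 9))):
        rows[t_i] = sorted(_internal_masks(tree, idx))
    if n <= 8:  # keep the big n=9 array out of the resident cache
        _MASK_CACHE[n] = rows
    return rows


def _tree_from_clades(clade_masks: Iterable[int], leaves: Sequence[str]) -> TreeNode:
    """Rebuild the unique binary topology whose nontrivial clades are given."""
    n = len(leaves)
    full = (1 << n) - 1
    nodes = sorted(set(clade_masks) | {full} | {1 << i for i in range(n)},
                   key=lambda m: bin(m).count("1"))
    built: dict[int, TreeNode] = {1 << i: leaves[i] for i in range(n)}
    for m in nodes:
        if m in built:
            continue
        # children = the two maximal already-built strict subsets of m
        rest = m
        kids: list[TreeNode] = []
        for sub in reversed([x for x in nodes if x != m and (x & m) == x]):
            if sub & rest == sub and sub in built:
                kids.append(built[sub])
                rest &= ~sub
                if rest == 0:
                    break
        if len(kids) != 2 or rest != 0:
            raise ValueError("clade set is not a binary laminar family")
        built[m] = (kids[0], kids[1])
    return canonicalize(built[full])


def _exhaustive_best(
    leaves: Sequence[str],
    patterns: Sequence[tuple[int, int, str]],
    chunk: int = 200_000,
) -> tuple[TreeNode, int]:
    n = len(leaves)
    base = sum(1 for c, a, _ in patterns if c & (c - 1) == 0 or a == 0)
    nontrivial = [(c, a) for c, a, _ in patterns if not (c & (c - 1) == 0 or a == 0)]
    all_masks = _topology_masks(n)
    n_trees = all_masks.shape[0]

    best_score = -1
    tied_rows: list[np.ndarray] = []
    for start in range(0, n_trees, chunk):
        masks = all_masks[start : start + chunk]
        scores = np.full(masks.shape[0], base, dtype=np.int64)
        for c, a in nontrivial:
            ok = ((masks & np.uint32(c)) == np.uint32(c)) & ((masks & np.uint32(a)) == 0)
            scores += ok.any(axis=1)
        local_max = int(scores.max()) if scores.size else base
        if local_max > best_score:
            best_score = local_max
            tied_rows = []
        if local_max == best_score:
            tied_rows.extend(masks[scores == best_score])

    # tie-break: lexicographically smallest canonical newick topology
    best_tree_: Optional[TreeNode] = None
    best_key: Optional[str] = None
    for row in tied_rows:
        t = _tree_from_clades((int(m) for m in row), list(leaves))
        key = _topology_newick(t)
        if best_key is None or key < best_key:
            best_key, best_tree_ = key, t
    assert best_tree_ is not None
    return best_tree_, best_score


# ---------------------------------------------------------------------------
# Hill climbing
# ---------------------------------------------------------------------------


def _upgma_start(presence: PresenceMatrix, leaves: Sequence[str]) -> TreeNode:
    """Average-linkage join tree on binary (Jaccard-mismatch) distances."""
    inc = (presence.states.loc[:, list(leaves)] == PRESENT).to_numpy(float)
    n = len(leaves)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(inc[:, i], inc[:, j]).sum()
            diff = (inc[:, i] != inc[:, j]).sum()
            dist[i, j] = dist[j, i] = diff / union if union else 0.0
    Z = linkage(squareform(dist, checks=False), method="average")
    nodes: dict[int, TreeNode] = {i: leaves[i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(Z):
        nodes[n + k] = (nodes[int(a)], nodes[int(b)])
    return canonicalize(nodes[n + len(Z) - 1])


def _hill_climb_best(
    presence: PresenceMatrix,
    leaves: Sequence[str],
    patterns: Sequence[tuple[int, int, str]],
    seed: int,
    restarts: int,
) -> tuple[TreeNode, int]:
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(leaves)}
    full = (1 << len(leaves)) - 1

    def score(t: TreeNode) -> int:
        return _score_topology(t, patterns, idx, full)

    starts: list[TreeNode] = [_upgma_start(presence, leaves)]
    starts.extend(random_topology(leaves, rng) for _ in range(max(restarts - 1, 0)))

    best_t: Optional[TreeNode] = None
    best_s = -1
    best_key = ""
    for start in starts:
        current, current_s = start, score(start)
        while True:
            improved = False
            for nb in spr_neighbors(current) + reroot_candidates(current):
                s = score(nb)
                if s > current_s:
                    current, current_s = nb, s
                    improved = True
            if not improved:
                break
        key = _topology_newick(canonicalize(current))
        if current_s > best_s or (current_s == best_s and key < best_key):
            best_t, best_s, best_key = canonicalize(current), current_s, key
    assert best_t is not None
    return best_t, best_s


# ---------------------------------------------------------------------------
# Result container and serialisation
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """A scored rooted sample tree with per-edge supporting mutations."""

    topology: TreeNode  # canonical nested tuples
    leaves: tuple[str, ...]
    clades: tuple[frozenset, ...]  # all 2n-1 clades; full set = trunk
    edge_mutations: dict[frozenset, tuple[str, ...]]
    score: int
    homoplasies: tuple[str, ...]
    n_characters: int
    method: str

    @property
    def edge_support(self) -> dict[frozenset, int]:
        return {clade: len(m) for clade, m in self.edge_mutations.items()}

    @property
    def trunk(self) -> frozenset:
        return frozenset(self.leaves)

    def supported_clades(self) -> dict[frozenset, int]:
        """Clades with at least one supporting mutation."""
        return {c: len(m) for c, m in self.edge_mutations.items() if m}


def _topology_newick(tree: TreeNode) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(_topology_newick(c) for c in tree) + ")"


def to_newick(ptree: PhyloTree) -> str:
    """Canonical newick with branch lengths = supporting-mutation counts.

    The trunk length (mutations of the ancestral clone) is written on the
    root; child order is by smallest leaf label for reproducibility.
    """
    support = ptree.edge_support

    def rec(node: TreeNode) -> tuple[str, frozenset]:
        if isinstance(node, str):
            return f"{node}:{support.get(frozenset([node]), 0)}", frozenset([node])
        parts, clade = [], frozenset()
        for child in node:
            txt, sub = rec(child)
            parts.append(txt)
            clade |= sub
        return "(" + ",".join(parts) + f"):{support.get(clade, 0)}", clade

    body, _ = rec(ptree.topology)
    return body + ";"


def best_tree(
    presence: PresenceMatrix,
    method: str = "auto",
    seed: int = 0,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    restarts: int = 10,
) -> PhyloTree:
    """Find the highest-scoring rooted sample tree.

    ``method`` is "exhaustive" (global optimum, up to ``exhaustive_limit``
    leaves), "hill_climb" (greedy ascent over subtree-prune-regraft and
    rerooting moves from an average-linkage join tree, with random
    restarts), or "auto" (exhaustive when feasible, otherwise falls back to
    hill climbing with a log message).  Deterministic given ``seed``.
    """
    leaves, patterns = _extract_patterns(presence)
    n = len(leaves)
    if method == "auto":
        if n <= exhaustive_limit:
            method = "exhaustive"
        else:
            logger.info(
                "phylogeny: %d samples exceed exhaustive limit %d; "
                "falling back to hill_climb", n, exhaustive_limit,
            )
            method = "hill_climb"
    if method == "exhaustive":
        if n > exhaustive_limit:
            raise ValueError(
                f"{n} samples exceed exhaustive limit {exhaustive_limit}; "
                "use method='hill_climb'"
            )
        topo, score = _exhaustive_best(leaves, patterns)
    elif method == "hill_climb":
        topo, score = _hill_climb_best(presence, leaves, patterns, seed, restarts)
    else:
        raise ValueError(f"unknown method {method!r}")

    total, assignment, homoplasies = score_tree(topo, presence)
    assert total == score, "edge assignment disagrees with search score"
    return PhyloTree(
        topology=topo,
        leaves=tuple(leaves),
        clades=tuple(assignment),
        edge_mutations={c: tuple(m) for c, m in assignment.items()},
        score=score,
        homoplasies=tuple(homoplasies),
        n_characters=len(patterns),
        method=method,
    )
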