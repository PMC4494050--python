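"""Dollo parsimony over binary presence/absence characters with missing data.

A retrotransposon insertion is a rare genomic event: it arises once on a single
branch and, at most, is subsequently lost.  Under Dollo parsimony a character
(one insertion locus, coded 1 = present, 0 = absent, ? = missing) therefore
costs one "gain" step on the branch above the most recent common ancestor of
all taxa that definitely carry it, plus one "loss" step for every maximal
subtree below that gain whose definite states are all absent.  Missing states
resolve cost-free.

Trees are rooted binary trees whose leaves are taxon names; character matrices
carry an artificial all-absent ancestor that roots the tree.  Tree search is
either exhaustive (all rooted ingroup topologies, feasible up to 9 leaves
including the ancestor) or heuristic (random-addition stepwise insertion
followed by subtree-prune-regraft hill climbing, which subsumes NNI moves).
Bootstrap support is the percentage of character-resampled replicates whose
set of equally best trees all contain a given ingroup clade (strict-consensus
counting, so ties never inflate support).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .errors import ConfigError, DataError

MISSING = "?"

# --------------------------------------------------------------------------
# Tree structure
# --------------------------------------------------------------------------


class Node:
    """A node of a rooted tree; leaves carry a taxon name."""

    __slots__ = ("name", "children", "label")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[List["Node"]] = None,
                 label: Optional[str] = None):
        self.name = name
        self.children = children or []
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree with optional internal-node labels and a Dollo score."""

    def __init__(self, root: Node, score: Optional[int] = None):
        self.root = root
        self.score = score

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)

        def conv(nd) -> Node:
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon is not None else nd.label
                if name is None:
                    raise DataError("unnamed leaf in newick input")
                return Node(name=str(name))
            return Node(children=[conv(c) for c in nd.child_nodes()],
                        label=str(nd.label) if nd.label else None)

        return cls(conv(dt.seed_node))

    @classmethod
    def from_tuples(cls, tup, ancestor: Optional[str] = None) -> "Tree":
        """Build from a nested-tuple topology; optionally attach an ancestor
        leaf as sister to the whole ingroup."""
        node = _tuple_to_node(tup)
        if ancestor is not None:
            node = Node(children=[Node(name=ancestor), node])
        return cls(node)

    # -- queries -----------------------------------------------------------

    def leaves(self) -> List[str]:
        out: List[str] = []

        def rec(n: Node):
            if n.is_leaf:
                out.append(n.name)
            else:
                for c in n.children:
                    rec(c)

        rec(self.root)
        return out

    def clades(self) -> set:
        """Leaf-name frozensets of every internal node (root included)."""
        out = set()

        def rec(n: Node) -> frozenset:
            if n.is_leaf:
                return frozenset([n.name])
            s = frozenset().union(*(rec(c) for c in n.children))
            out.add(s)
            return s

        rec(self.root)
        return out

    def ingroup_clades(self, ancestor: str) -> set:
        """Non-trivial ingroup clades (2 <= size <= n_ingroup - 1)."""
        leaves = set(self.leaves()) - {ancestor}
        out = set()
        for c in self.clades():
            c = frozenset(c - {ancestor})
            if 2 <= len(c) <= len(leaves) - 1:
                out.add(c)
        return out

    def to_newick(self) -> str:
        def rec(n: Node) -> str:
            if n.is_leaf:
                return n.name
            inner = ",".join(rec(c) for c in n.children)
            lab = n.label if n.label is not None else ""
            return f"({inner}){lab}"

        return rec(self.root) + ";"

    def same_topology(self, other: "Tree") -> bool:
        return (set(self.leaves()) == set(other.leaves())
                and self.clades() == other.clades())

    def copy(self) -> "Tree":
        def rec(n: Node) -> Node:
            return Node(name=n.name, label=n.label,
                        children=[rec(c) for c in n.children])

        return Tree(rec(self.root), score=self.score)


def _tuple_to_node(t) -> Node:
    if isinstance(t, str):
        return Node(name=t)
    return Node(children=[_tuple_to_node(x) for x in t])


# --------------------------------------------------------------------------
# Compiled scoring core
#
# A compiled tree is a nested pair (leafset_bitmask, children_tuple); a
# character is a pair of bitmasks (ones, zeros) over the taxon order.  This
# keeps scoring allocation-free in the search inner loop.
# --------------------------------------------------------------------------


def _compile_node(n: Node, bit: Mapping[str, int]):
    if n.is_leaf:
        try:
            return (bit[n.name], ())
        except KeyError:
            raise DataError(f"leaf {n.name!r} not present in taxon set")
    kids = tuple(_compile_node(c, bit) for c in n.children)
    mask = 0
    for k in kids:
        mask |= k[0]
    return (mask, kids)


def _compile_tuple(t, bit: Mapping[str, int]):
    if isinstance(t, str):
        return (bit[t], ())
    kids = tuple(_compile_tuple(x, bit) for x in t)
    mask = 0
    for k in kids:
        mask |= k[0]
    return (mask, kids)


def _losses(comp, ones: int, zeros: int) -> int:
    total = 0
    for ch in comp[1]:
        m = ch[0]
        if m & ones:
            total += _losses(ch, ones, zeros)
        elif m & zeros:
            total += 1
        # else: subtree entirely missing -> resolves as present, cost-free
    return total


def _char_steps(comp, ones: int, zeros: int) -> int:
    if not ones:
        return 0
    node = comp
    while True:  # descend to the MRCA of all definite presences
        nxt = None
        for ch in node[1]:
            if ch[0] & ones == ones:
                nxt = ch
                break
        if nxt is None:
            break
        node = nxt
    return 1 + _losses(node, ones, zeros)


def _state_masks(states: Sequence[str], ) -> Tuple[int, int]:
    ones = zeros = 0
    for i, s in enumerate(states):
        if s in (1, "1"):
            ones |= 1 << i
        elif s in (0, "0"):
            zeros |= 1 << i
        elif s not in (MISSING, None):
            raise DataError(f"invalid character state {s!r}")
    return ones, zeros


# --------------------------------------------------------------------------
# Public scoring API
# --------------------------------------------------------------------------


def dollo_char_score(tree: Tree, states: Mapping[str, object]) -> int:
    """Dollo steps (one gain plus losses) for a single character.

    ``states`` maps every leaf name to 1/0/'?' (ints or single-character
    strings).  The character is assumed absent above the root, so a gain on
    the root edge costs one step like any other.
    """
    leaves = tree.leaves()
    missing = [lf for lf in leaves if lf not in states]
    if missing:
        raise DataError(f"states missing for leaves: {missing}")
    bit = {lf: 1 << i for i, lf in enumerate(leaves)}
    comp = _compile_node(tree.root, bit)
    ones, zeros = _state_masks([_norm_state(states[lf]) for lf in leaves])
    return _char_steps(comp, ones, zeros)


def _norm_state(s) -> str:
    if s in (1, "1"):
        return "1"
    if s in (0, "0"):
        return "0"
    if s in (MISSING, None):
        return MISSING
    raise DataError(f"invalid character state {s!r}")


def _matrix_patterns(matrix) -> Tuple[List[str], List[Tuple[int, int]], np.ndarray]:
    """Pattern-compress a CharacterMatrix.

    Returns (taxa, [(ones, zeros), ...], weights) where identical columns are
    batched with their multiplicity.
    """
    taxa = list(matrix.taxa)
    arr = matrix.states
    counts: Dict[Tuple[str, ...], int] = {}
    for j in range(arr.shape[1]):
        col = tuple(arr[:, j])
        counts[col] = counts.get(col, 0) + 1
    pats = []
    weights = []
    for col, w in counts.items():
        pats.append(_state_masks(col))
        weights.append(w)
    return taxa, pats, np.asarray(weights, dtype=np.int64)


def tree_score(tree: Tree, matrix) -> int:
    """Total Dollo steps of a character matrix on a tree (equal weights).

    Identical columns are pattern-compressed before scoring; the total is
    identical to scoring every column independently.
    """
    taxa = list(matrix.taxa)
    if set(taxa) != set(tree.leaves()):
        raise DataError("matrix taxa and tree leaves differ")
    bit = {t: 1 << i for i, t in enumerate(taxa)}
    comp = _compile_node(tree.root, bit)
    _, pats, weights = _matrix_patterns(matrix)
    return int(sum(int(w) * _char_steps(comp, o, z)
                   for (o, z), w in zip(pats, weights)))


# --------------------------------------------------------------------------
# Topology enumeration (rooted ingroup trees as nested tuples)
# --------------------------------------------------------------------------


def _insertions(t, leaf):
    """All trees obtained by inserting ``leaf`` on any edge of ``t``
    (including the edge above the root)."""
    yield (t, leaf)
    if isinstance(t, tuple):
        a, b = t
        for na in _insertions(a, leaf):
            yield (na, b)
        for nb in _insertions(b, leaf):
            yield (a, nb)


def enumerate_rooted_topologies(leaves: Sequence[str]) -> Iterator:
    """All (2n-3)!! rooted binary topologies over the given leaf names."""
    leaves = sorted(leaves)
    if not leaves:
        return
    if len(leaves) == 1:
        yield leaves[0]
        return

    def rec(i, tree):
        if i == len(leaves):
            yield tree
            return
        for t in _insertions(tree, leaves[i]):
            yield from rec(i + 1, t)

    yield from rec(1, leaves[0])


def _canon(t):
    if isinstance(t, str):
        return t
    a, b = _canon(t[0]), _canon(t[1])
    return (a, b) if repr(a) <= repr(b) else (b, a)


def _spr_neighbors(t):
    """Subtree-prune-regraft neighborhood of a rooted tuple tree (includes
    all NNI rearrangements as a subset)."""
    out = set()

    def prunes(tt):
        # yields (pruned_subtree, remainder_tree)
        if isinstance(tt, str):
            return
        a, b = tt
        yield a, b
        yield b, a
        for s, ra in prunes(a):
            yield s, (ra, b)
        for s, rb in prunes(b):
            yield s, (a, rb)

    for sub, rem in prunes(t):
        for nt in _insertions(rem, sub):
            out.add(_canon(nt))
    out.discard(_canon(t))
    return out


# --------------------------------------------------------------------------
# Tree search
# --------------------------------------------------------------------------

MAX_EXHAUSTIVE_LEAVES = 9  # including the artificial ancestor


def _search_setup(matrix):
    anc = matrix.ancestor
    taxa = list(matrix.taxa)
    if anc not in taxa:
        raise DataError("matrix has no ancestor row")
    ingroup = [t for t in taxa if t != anc]
    bit = {t: 1 << i for i, t in enumerate(taxa)}
    _, pats, weights = _matrix_patterns(matrix)
    return anc, ingroup, bit, pats, weights


def _score_tuple(tup, anc, bit, pats, weights) -> int:
    comp = _compile_tuple(((anc, tup) if len(bit) > 1 else tup), bit)
    return int(sum(int(w) * _char_steps(comp, o, z)
                   for (o, z), w in zip(pats, weights)))


def search_trees(matrix, strategy: str = "exhaustive",
                 n_random_addition: int = 10,
                 seed: Optional[int] = None) -> Tuple[List[Tree], int]:
    """Find minimum-Dollo-score trees rooted on the all-absent ancestor.

    exhaustive: enumerate every rooted ingroup topology (refused above
    9 leaves total) and return *all* minimum-score trees.
    heuristic: stepwise addition in seeded random leaf order followed by
    SPR hill climbing, best over ``n_random_addition`` replicates; returns a
    single best tree.
    """
    anc, ingroup, bit, pats, weights = _search_setup(matrix)
    if len(ingroup) < 3:
        raise DataError("need at least 4 taxa including the ancestor")

    if strategy == "exhaustive":
        if len(ingroup) + 1 > MAX_EXHAUSTIVE_LEAVES:
            raise ConfigError(
                f"exhaustive search supports at most {MAX_EXHAUSTIVE_LEAVES} "
                f"leaves including the ancestor; use strategy='heuristic'")
        best: Optional[int] = None
        best_tups: List = []
        for tup in enumerate_rooted_topologies(ingroup):
            s = _score_tuple(tup, anc, bit, pats, weights)
            if best is None or s < best:
                best, best_tups = s, [tup]
            elif s == best:
                best_tups.append(tup)
        trees = [Tree.from_tuples(t, ancestor=anc) for t in best_tups]
        for t in trees:
            t.score = best
        return trees, int(best)

    if strategy != "heuristic":
        raise ConfigError(f"unknown search strategy {strategy!r}")

    rng = np.random.default_rng(seed)
    best = None
    best_tup = None
    for _ in range(n_random_addition):
        order = list(ingroup)
        rng.shuffle(order)
        tree = (order[0], order[1])
        for leaf in order[2:]:
            tree = min(_insertions(tree, leaf),
                       key=lambda t: (_score_tuple(t, anc, bit, pats, weights),
                                      repr(_canon(t))))
        score = _score_tuple(tree, anc, bit, pats, weights)
        improved = True
        while improved:
            improved = False
            for nb in sorted(_spr_neighbors(tree), key=repr):
                s = _score_tuple(nb, anc, bit, pats, weights)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        if best is None or score < best:
            best, best_tup = score, tree
    out = Tree.from_tuples(best_tup, ancestor=anc)
    out.score = int(best)
    return [out], int(best)


# --------------------------------------------------------------------------
# Bootstrap
# --------------------------------------------------------------------------


def _tuple_clades(tup, ingroup_size: int) -> frozenset:
    """Non-trivial ingroup clades of a tuple topology."""
    out = set()

    def rec(t) -> frozenset:
        if isinstance(t, str):
            return frozenset([t])
        s = rec(t[0]) | rec(t[1])
        out.add(s)
        return s

    rec(tup)
    return frozenset(c for c in out if 2 <= len(c) <= ingroup_size - 1)


def bootstrap(matrix, n_replicates: int, strategy: str = "exhaustive",
              n_random_addition: int = 10,
              seed: Optional[int] = None) -> Tuple[Dict[frozenset, float], Tree]:
    """Character-resampling bootstrap.

    Each replicate resamples columns with replacement to the original count,
    re-runs the search, and a clade is counted when it appears in every
    equally best tree of the replicate.  Returns (clade -> percent support,
    best tree from the full matrix with internal nodes labeled).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    anc, ingroup, bit, pats, weights = _search_setup(matrix)
    rng = np.random.default_rng(seed)
    n_char = int(weights.sum())
    probs = weights / n_char

    counts: Dict[frozenset, int] = {}

    if strategy == "exhaustive" and len(ingroup) + 1 <= MAX_EXHAUSTIVE_LEAVES:
        topologies = list(enumerate_rooted_topologies(ingroup))
        smat = np.empty((len(topologies), len(pats)), dtype=np.int64)
        for i, tup in enumerate(topologies):
            comp = _compile_tuple((anc, tup), bit)
            for j, (o, z) in enumerate(pats):
                smat[i, j] = _char_steps(comp, o, z)
        full_scores = smat @ weights
        best_full = int(full_scores.min())
        best_idx = int(np.argmin(full_scores))
        best_tree = Tree.from_tuples(topologies[best_idx], ancestor=anc)
        best_tree.score = best_full

        clade_cache: Dict[int, frozenset] = {}
        rep_weights = rng.multinomial(n_char, probs, size=n_replicates)
        rep_scores = smat @ rep_weights.T  # (n_topologies, n_replicates)
        for r in range(n_replicates):
            col = rep_scores[:, r]
            ties = np.flatnonzero(col == col.min())
            common: Optional[frozenset] = None
            for i in map(int, ties):
                if i not in clade_cache:
                    clade_cache[i] = _tuple_clades(topologies[i], len(ingroup))
                cl = clade_cache[i]
                common = cl if common is None else (common & cl)
                if not common:
                    break
            for c in common or ():
                counts[c] = counts.get(c, 0) + 1
    else:
        best_trees, best_full = search_trees(
            matrix, strategy="heuristic",
            n_random_addition=n_random_addition, seed=int(rng.integers(2**31)))
        best_tree = best_trees[0]
        for _ in range(n_replicates):
            sub = matrix.resample_columns(int(rng.integers(2**31)))
            trees, _ = search_trees(
                sub, strategy="heuristic",
                n_random_addition=n_random_addition,
                seed=int(rng.integers(2**31)))
            for c in trees[0].ingroup_clades(anc):
                counts[c] = counts.get(c, 0) + 1

    support = {c: 100.0 * n / n_replicates for c, n in counts.items()}
    _label_supports(best_tree, anc, support)
    return support, best_tree


def _label_supports(tree: Tree, ancestor: str, support: Mapping[frozenset, float]):
    n_in = len(set(tree.leaves()) - {ancestor})

    def rec(n: Node) -> frozenset:
        if n.is_leaf:
            return frozenset([n.name])
        s = frozenset().union(*(rec(c) for c in n.children))
        clade = frozenset(s - {ancestor})
        if 2 <= len(clade) <= n_in - 1 and clade in support:
            n.label = f"{support[clade]:g}"
        return s

    rec(tree.root)


# --------------------------------------------------------------------------
# Parsimony statistics
# --------------------------------------------------------------------------


@dataclass
class ParsimonyStats:
    """Standard parsimony fit indices for a scored tree.

    length: total Dollo steps S.  M / G are the per-character minimum and
    maximum conceivable steps summed over characters (per character: m = 1 if
    it has any definite presence; g = 1 + number of definite-absence ingroup
    leaves, the worst-case single-gain arrangement).  CI = M/S, HI = 1-CI,
    RI = (G-S)/(G-M), RC = CI*RI.
    """

    length: int
    min_steps: int
    max_steps: int
    ci: float
    ri: float
    rc: float
    hi: float
    degenerate: bool = False


def parsimony_stats(tree: Tree, matrix) -> ParsimonyStats:
    s = tree_score(tree, matrix)
    taxa = list(matrix.taxa)
    anc_i = taxa.index(matrix.ancestor)
    m_total = 0
    g_total = 0
    arr = matrix.states
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if not (col == "1").any():
            continue
        m_total += 1
        n_zero_ingroup = int(sum(1 for i, st in enumerate(col)
                                 if i != anc_i and st == "0"))
        g_total += 1 + n_zero_ingroup
    if s == 0:
        return ParsimonyStats(0, m_total, g_total, 1.0, 1.0, 1.0, 0.0,
                              degenerate=True)
    ci = m_total / s
    ri = (g_total - s) / (g_total - m_total) if g_total > m_total else 1.0
    return ParsimonyStats(s, m_total, g_total, ci, ri, ci * ri, 1.0 - ci)


# --------------------------------------------------------------------------
# Brute-force reference scorer (testing oracle)
# --------------------------------------------------------------------------


def brute_force_char_score(tree: Tree, states: Mapping[str, object]) -> int:
    """Minimum steps over every Dollo-valid assignment of ancestral states.

    Enumerates presence/absence at every node (missing leaves are free),
    requires at most one absent-to-present transition counting the phantom
    edge above the root, and minimizes the number of state-change edges.
    Exponential; intended for small trees in tests only.
    """
    nodes: List[Node] = []
    parent: Dict[int, Optional[int]] = {}

    def rec(n: Node, p: Optional[int]):
        i = len(nodes)
        nodes.append(n)
        parent[i] = p
        for c in n.children:
            rec(c, i)

    rec(tree.root, None)
    fixed: Dict[int, int] = {}
    free: List[int] = []
    for i, n in enumerate(nodes):
        if n.is_leaf:
            st = _norm_state(states[n.name])
            if st == MISSING:
                free.append(i)
            else:
                fixed[i] = int(st)
        else:
            free.append(i)

    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        steps = assign[0]          # phantom edge above root (ancestrally absent)
        gains = assign[0]
        ok = True
        for i in range(1, len(nodes)):
            p = assign[parent[i]]
            c = assign[i]
            if c != p:
                steps += 1
                if c == 1:
                    gains += 1
                    if gains > 1:
                        ok = False
                        break
        if ok and (best is None or steps < best):
            best = steps
    return int(best)
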