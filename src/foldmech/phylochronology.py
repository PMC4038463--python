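"""Relative ages of domain structures from an abundance census.

The model: genomic abundance of a domain structure grows with evolutionary
time (duplication outpaces loss), so abundance is treated as a polarized,
ordered multistate phylogenetic character.  Each proteome contributes one
character; per character the abundance is log-rescaled onto integer states
``0 .. n_states-1`` and the maximum state ``N = n_states-1`` is declared
ancestral (character polarization N -> 0).  Rooted trees of structures
(taxa) are sought under Wagner parsimony — an ordered character changing
from state *i* to *j* costs ``|i - j|`` — with the root constrained to the
all-ancestral state, which is equivalent to attaching a hypothetical all-N
outgroup (Lundberg rooting).

A structure's relative age is its *node distance* ``nd``: the number of
internal nodes on the root-to-leaf path, rescaled to [0, 1] over the tree
(0 = oldest, 1 = youngest).  A linear molecular clock of folds converts
``nd`` to geological time, ``age_ga = 3.8 * (1 - nd)`` billion years, with
``nd = 0`` anchored at the origin of proteins ~3.8 Ga.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from foldmech.io import AbundanceCensus
from foldmech.tree import TreeNode

logger = logging.getLogger(__name__)

#: age of the origin of proteins used by the molecular clock of folds, in Ga
CLOCK_ORIGIN_GA = 3.8

DEFAULT_N_STATES = 24
MAX_EXACT_TAXA = 7  # exhaustive topology search up to this many taxa


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class CodedCharacterMatrix:
    """Integer state matrix: rows = structures (taxa), columns = proteomes
    (characters), states ``0..n_states-1`` with the maximum state ancestral."""

    def __init__(self, table: pd.DataFrame, n_states: int):
        values = table.to_numpy()
        if values.size and (values.min() < 0 or values.max() > n_states - 1):
            raise ValueError("state out of range for n_states")
        self.table = table.astype(np.int64)
        self.n_states = int(n_states)

    @property
    def ancestral_state(self) -> int:
        return self.n_states - 1

    @property
    def taxa(self) -> list:
        return list(self.table.index)

    def states_for(self, taxa: Sequence[str]) -> np.ndarray:
        return self.table.loc[list(taxa)].to_numpy()


class AgeTable:
    """Per-structure relative age ``nd`` in [0, 1] and geological age in Ga."""

    def __init__(self, nd: pd.Series):
        nd = nd.astype(float)
        if ((nd < 0) | (nd > 1)).any():
            raise ValueError("nd values must lie in [0, 1]")
        if nd.index.duplicated().any():
            raise ValueError("duplicate structure ids in age table")
        self.nd = nd.rename("nd")

    @property
    def age_ga(self) -> pd.Series:
        return nd_to_age_ga(self.nd).rename("age_ga")

    def __len__(self) -> int:
        return len(self.nd)

    def __contains__(self, cath_id: object) -> bool:
        return cath_id in self.nd.index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"nd": self.nd, "age_ga": self.age_ga})


# ---------------------------------------------------------------------------
# character coding
# ---------------------------------------------------------------------------

def code_characters(census: AbundanceCensus,
                    n_states: int = DEFAULT_N_STATES) -> CodedCharacterMatrix:
    """Log-rescale abundances onto ``0..n_states-1`` per proteome column.

    Abundance ``a`` in a column with maximum ``a_max`` maps to
    ``round(ln(1+a) / ln(1+a_max) * (n_states-1))``; the log tames the
    heavy-tailed abundance distribution before linear binning.  Columns whose
    maximum is 0 carry no signal and are dropped with a warning.
    """
    if not 2 <= n_states <= 24:
        raise ValueError("n_states must be between 2 and 24")
    table = census.table
    col_max = table.max(axis=0)
    dead = col_max[col_max == 0].index
    if len(dead):
        logger.warning("dropping %d all-zero proteome column(s)", len(dead))
        table = table.drop(columns=dead)
        col_max = col_max.drop(dead)
    a = table.to_numpy(dtype=float)
    denom = np.log1p(col_max.to_numpy(dtype=float))
    states = np.rint(np.log1p(a) / denom * (n_states - 1)).astype(np.int64)
    coded = pd.DataFrame(states, index=table.index, columns=table.columns)
    return CodedCharacterMatrix(coded, n_states)


# ---------------------------------------------------------------------------
# Wagner parsimony scoring
# ---------------------------------------------------------------------------

def parsimony_score(tree: TreeNode, coded: CodedCharacterMatrix) -> int:
    """Minimum total cost of the tree under polarized ordered parsimony.

    Sankoff dynamic programming over states at internal nodes with linear
    step cost ``|i - j|``; the root is constrained to the ancestral state
    ``N`` (polarization).  Handles arbitrary (including non-binary) rooted
    trees.
    """
    leaf_labels = set(tree.leaf_labels())
    matrix_taxa = set(coded.taxa)
    missing = leaf_labels - matrix_taxa
    if missing:
        raise KeyError(f"tree leaf/leaves without a matrix row: {sorted(missing)}")

    n_states = coded.n_states
    n_chars = coded.table.shape[1]
    states_by_taxon = {t: coded.table.loc[t].to_numpy() for t in leaf_labels}
    big = np.iinfo(np.int64).max // 4

    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = np.full((n_states, n_chars), big, dtype=np.int64)
            c[states_by_taxon[node.label], np.arange(n_chars)] = 0
        else:
            c = np.zeros((n_states, n_chars), dtype=np.int64)
            for child in node.children:
                c += _min_plus_linear(costs.pop(id(child)))
        costs[id(node)] = c
    root_cost = costs[id(tree)]
    return int(root_cost[coded.ancestral_state].sum())


def _min_plus_linear(c: np.ndarray) -> np.ndarray:
    """Given child state costs ``c[j, char]`` return
    ``m[i, char] = min_j c[j, char] + |i - j|`` via two running-minimum
    sweeps (the lower envelope of a linear-cost transform)."""
    m = c.copy()
    for i in range(1, m.shape[0]):          # j <= i
        np.minimum(m[i], m[i - 1] + 1, out=m[i])
    for i in range(m.shape[0] - 2, -1, -1):  # j >= i
        np.minimum(m[i], m[i + 1] + 1, out=m[i])
    return m


def _wagner_score_binary(root: TreeNode, states_by_taxon: dict,
                         ancestral_state: int) -> int:
    """Fast exact Wagner score for strictly bifurcating rooted trees.

    Farris interval method: each node carries a state interval per character;
    two child intervals that overlap cost nothing and intersect, disjoint
    intervals cost the gap between them and the node takes the gap interval.
    The root pays its distance to the ancestral state.  Equals the Sankoff
    score on binary trees for ordered characters.
    """
    total = 0
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node in root.postorder():
        if node.is_leaf:
            s = states_by_taxon[node.label]
            lo[id(node)] = s
            hi[id(node)] = s
        elif node is root:
            # polarized root: the state is fixed at N, so each child simply
            # pays its distance to N (beyond its minimizer interval the
            # child's transformed cost rises with slope exactly 1; summing
            # intervals here and measuring one distance would undercount)
            for child in node.children:
                lc, hc = lo.pop(id(child)), hi.pop(id(child))
                total += int(np.maximum(lc - ancestral_state, 0).sum()
                             + np.maximum(ancestral_state - hc, 0).sum())
        else:
            a, b = node.children
            la, ha = lo.pop(id(a)), hi.pop(id(a))
            lb, hb = lo.pop(id(b)), hi.pop(id(b))
            nlo = np.maximum(la, lb)
            nhi = np.minimum(ha, hb)
            gap = nlo - nhi
            gap_pos = gap > 0
            total += int(gap[gap_pos].sum())
            # disjoint intervals: node interval spans the gap
            nlo2 = np.where(gap_pos, nhi, nlo)
            nhi2 = np.where(gap_pos, nlo, nhi)
            lo[id(node)] = nlo2
            hi[id(node)] = nhi2
    return total


# ---------------------------------------------------------------------------
# topology enumeration and rearrangement
# ---------------------------------------------------------------------------

def enumerate_rooted_trees(labels: Sequence[str]):
    """Yield every rooted bifurcating topology on ``labels``
    ((2n-3)!! of them), by recursive edge insertion."""
    labels = list(labels)
    if not labels:
        return
    if len(labels) == 1:
        yield TreeNode(labels[0])
        return

    def build(tree: TreeNode, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        label = remaining[0]
        rest = remaining[1:]
        for placed in _all_insertions(tree, label):
            yield from build(placed, rest)

    base = TreeNode(children=[TreeNode(labels[0]), TreeNode(labels[1])])
    yield from build(base, labels[2:])


def _all_insertions(tree: TreeNode, label: str):
    """All trees obtained by grafting leaf ``label`` onto an edge of ``tree``
    (including above the root)."""
    out = [TreeNode(children=[tree.copy(), TreeNode(label)])]
    nodes = [n for n in tree.postorder()]
    for target in nodes:
        if target is tree:
            continue
        t = tree.copy()
        # find the copied counterpart by parallel traversal
        orig_nodes = list(tree.postorder())
        copy_nodes = list(t.postorder())
        target_copy = copy_nodes[orig_nodes.index(target)]
        _graft_above(t, target_copy, TreeNode(label))
        out.append(t)
    return out


def _graft_above(root: TreeNode, target: TreeNode, leaf: TreeNode) -> None:
    for node in root.postorder():
        for i, child in enumerate(node.children):
            if child is target:
                node.children[i] = TreeNode(children=[child, leaf])
                return
    raise ValueError("target not found")  # pragma: no cover


def _nni_neighbors(root: TreeNode):
    """Yield rooted-NNI neighbours: for every internal non-root node, swap
    one of its children with its sibling."""
    parent_of = {}
    for node in root.postorder():
        for child in node.children:
            parent_of[id(child)] = node
    internal = [n for n in root.postorder()
                if not n.is_leaf and n is not root]
    for node in internal:
        parent = parent_of[id(node)]
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sibling = siblings[0]
        for k in range(len(node.children)):
            t = root.copy()
            orig = list(root.postorder())
            cop = list(t.postorder())
            node_c = cop[orig.index(node)]
            parent_c = cop[orig.index(parent)]
            sibling_c = cop[orig.index(sibling)]
            child_c = node_c.children[k]
            node_c.children[k] = sibling_c
            parent_c.children[parent_c.children.index(sibling_c)] = child_c
            yield t


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------

def search_mp_tree(coded: CodedCharacterMatrix, n_starts: int = 25,
                   seed: Optional[int] = None) -> TreeNode:
    """Best rooted tree under polarized Wagner parsimony.

    Exhaustive topology enumeration when the matrix has at most
    ``MAX_EXACT_TAXA`` taxa; otherwise ``n_starts`` replicates of random
    stepwise taxon addition followed by nearest-neighbour-interchange hill
    climbing.  Among equally parsimonious trees the one with the
    lexicographically smallest canonical Newick string is returned, making
    the output deterministic for a given seed.
    """
    taxa = coded.taxa
    if len(taxa) < 3:
        raise ValueError("tree search needs at least 3 taxa")
    states_by_taxon = {t: coded.table.loc[t].to_numpy() for t in taxa}
    anc = coded.ancestral_state

    def score(t: TreeNode) -> int:
        return _wagner_score_binary(t, states_by_taxon, anc)

    best_tree: Optional[TreeNode] = None
    best_score = None
    best_canon = None

    def consider(t: TreeNode, s: int):
        nonlocal best_tree, best_score, best_canon
        if best_score is None or s < best_score:
            best_tree, best_score, best_canon = t, s, t.canonical_newick()
        elif s == best_score:
            canon = t.canonical_newick()
            if canon < best_canon:
                best_tree, best_canon = t, canon

    if len(taxa) <= MAX_EXACT_TAXA:
        for t in enumerate_rooted_trees(sorted(taxa)):
            consider(t, score(t))
        return best_tree.canonicalise()

    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        order = [str(x) for x in rng.permutation(taxa)]
        t = _stepwise_addition(order, score)
        t, s = _nni_hill_climb(t, score)
        consider(t, s)
    return best_tree.canonicalise()


def _stepwise_addition(order: Sequence[str], score) -> TreeNode:
    tree = TreeNode(children=[TreeNode(order[0]), TreeNode(order[1])])
    for label in order[2:]:
        best = None
        best_s = None
        for candidate in _all_insertions(tree, label):
            s = score(candidate)
            if best_s is None or s < best_s:
                best, best_s = candidate, s
        tree = best
    return tree


def _nni_hill_climb(tree: TreeNode, score):
    current, current_s = tree, score(tree)
    improved = True
    while improved:
        improved = False
        for neighbor in _nni_neighbors(current):
            s = score(neighbor)
            if s < current_s:
                current, current_s = neighbor, s
                improved = True
                break
    return current, current_s


def random_tree(labels: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Uniform-ish random rooted bifurcating tree by random sequential
    grafting; used for null comparisons and property tests."""
    order = [str(x) for x in rng.permutation(list(labels))]
    tree = TreeNode(children=[TreeNode(order[0]), TreeNode(order[1])])
    for label in order[2:]:
        candidates = _all_insertions(tree, label)
        tree = candidates[rng.integers(len(candidates))]
    return tree


# ---------------------------------------------------------------------------
# node-distance ages and the molecular clock
# ---------------------------------------------------------------------------

def compute_nd(tree: TreeNode) -> AgeTable:
    """Relative node distance per leaf.

    ``d(leaf)`` counts the internal nodes on the root-to-leaf path (root
    included); ``nd = (d - d_min) / (d_max - d_min)``.  The affine rescale
    makes the internal-node counting convention immaterial.  A tree in which
    all leaves are equally deep carries no age signal: all ``nd`` are set to
    0 with a warning.
    """
    if not isinstance(tree, TreeNode):
        raise TypeError("compute_nd expects a rooted TreeNode")
    depths: dict[str, int] = {}

    stack = [(tree, 1 if not tree.is_leaf else 0)]
    if tree.is_leaf:
        return AgeTable(pd.Series({tree.label: 0.0}, name="nd"))
    while stack:
        node, d = stack.pop()
        for child in node.children:
            if child.is_leaf:
                depths[child.label] = d
            else:
                stack.append((child, d + 1))
    s = pd.Series(depths, dtype=float)
    d_min, d_max = s.min(), s.max()
    if d_max == d_min:
        warnings.warn("all leaves equally deep; nd set to 0 for every leaf")
        return AgeTable(pd.Series(0.0, index=s.index, name="nd"))
    return AgeTable((s - d_min) / (d_max - d_min))


def nd_to_age_ga(nd):
    """Molecular clock of folds: ``age_ga = 3.8 * (1 - nd)``, linear in nd,
    with nd = 0 at the origin of proteins (~3.8 Ga) and nd = 1 the present."""
    arr = np.asarray(nd, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("nd must lie in [0, 1]")
    result = CLOCK_ORIGIN_GA * (1.0 - arr)
    if isinstance(nd, pd.Series):
        return pd.Series(result, index=nd.index)
    if np.isscalar(nd) or arr.ndim == 0:
        return float(result)
    return result


def brute_force_parsimony(tree: TreeNode, coded: CodedCharacterMatrix) -> int:
    """Independent oracle: minimise total |i-j| cost over every assignment of
    states to internal nodes (root fixed at the ancestral state).  Only
    feasible for a handful of taxa; used to validate the DP scorers."""
    internal = [n for n in tree.postorder() if not n.is_leaf and n is not tree]
    parent_of = {}
    for node in tree.postorder():
        for child in node.children:
            parent_of[id(child)] = node
    leaves = tree.leaves()
    n_chars = coded.table.shape[1]
    anc = coded.ancestral_state
    total = 0
    for char in range(n_chars):
        leaf_state = {id(l): int(coded.table.loc[l.label].iloc[char])
                      for l in leaves}
        best = None
        for assignment in itertools.product(range(coded.n_states),
                                            repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assignment)}
            state[id(tree)] = anc
            state.update(leaf_state)
            cost = sum(abs(state[id(c)] - state[id(parent_of[id(c)])])
                       for c in tree.postorder() if c is not tree)
            if best is None or cost < best:
                best = cost
        total += best
    return total
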