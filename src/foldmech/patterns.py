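"""Combinatorial mechanistic annotation patterns, Jaccard similarity and
deterministic average-linkage clustering.

A *pattern* is the exact set of step types a structure (or enzyme-domain
pair) uses, irrespective of step order; structures sharing a pattern have
recruited an identical chemical repertoire.  Patterns partition the matrix
rows.  Pattern numbering here is canonical — ascending (set size, then the
lexicographically sorted key) — because any printed numbering of patterns is
dataset-specific; consumers should match patterns by key content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from foldmech.io import StepTypeVocabulary
from foldmech.mapping import StructureStepMatrix


@dataclass(frozen=True)
class Pattern:
    pattern_number: int
    key: tuple          # lexicographically sorted step-type names
    members: frozenset  # row ids whose full type set equals the key

    @property
    def size(self) -> int:
        return len(self.key)

    @property
    def n_members(self) -> int:
        return len(self.members)


class PatternTable:
    def __init__(self, patterns: Sequence[Pattern]):
        self.patterns = list(patterns)
        self._by_key = {p.key: p for p in self.patterns}

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def get(self, key) -> Optional[Pattern]:
        return self._by_key.get(tuple(sorted(key)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.pattern_number, p.size, ";".join(p.key), p.n_members,
              ";".join(sorted(str(m) for m in p.members)))
             for p in self.patterns],
            columns=["pattern_number", "size", "key", "member_count",
                     "members"])


class SimilarityMatrix:
    """Square symmetric matrix of Jaccard coefficients, diagonal exactly 1."""

    def __init__(self, table: pd.DataFrame):
        values = table.to_numpy(dtype=float)
        if table.shape[0] != table.shape[1] or \
                list(table.index) != list(table.columns):
            raise ValueError("similarity matrix must be square with matching labels")
        if not np.allclose(values, values.T):
            raise ValueError("similarity matrix must be symmetric")
        if len(table) and not np.all(np.diag(values) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        if values.size and (values.min() < 0 or values.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        self.table = table.astype(float)

    @property
    def ids(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

def extract_patterns(matrix: StructureStepMatrix) -> PatternTable:
    """Group matrix rows by their exact step-type set."""
    if not len(matrix):
        raise ValueError("empty matrix")
    groups: dict[tuple, set] = {}
    for row_id in matrix.row_ids:
        key = tuple(sorted(matrix.row_types(row_id)))
        groups.setdefault(key, set()).add(row_id)
    ordered = sorted(groups, key=lambda k: (len(k), k))
    return PatternTable([
        Pattern(i + 1, key, frozenset(groups[key]))
        for i, key in enumerate(ordered)])


def pattern_stats(table: PatternTable,
                  vocabulary: Optional[StepTypeVocabulary] = None) -> dict:
    """Summary counts over a pattern table.

    Returns ``n_patterns``, ``n_singleton_patterns`` (patterns unique to one
    row), ``n_rows`` and ``histogram`` — rows binned by the size of their
    step-type set.
    """
    hist: dict[int, int] = {}
    for p in table:
        hist[p.size] = hist.get(p.size, 0) + p.n_members
    return {
        "n_patterns": len(table),
        "n_singleton_patterns": sum(1 for p in table if p.n_members == 1),
        "n_rows": sum(p.n_members for p in table),
        "histogram": pd.Series(hist).sort_index(),
    }


def member_count(table: PatternTable, query: Sequence[str],
                 vocabulary: StepTypeVocabulary) -> int:
    """Number of rows whose full type set equals ``query`` exactly."""
    unknown = set(query) - set(vocabulary.names)
    if unknown:
        raise ValueError(f"query contains unknown step type(s): {sorted(unknown)}")
    pattern = table.get(query)
    return pattern.n_members if pattern else 0


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------

def jaccard_matrix(matrix: StructureStepMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard coefficient J(A,B) = |A∩B| / |A∪B| over row type
    sets.  Rows are guaranteed nonempty by the matrix invariant, so J is
    always defined; J = 1 iff two rows carry identical type sets."""
    if not len(matrix):
        raise ValueError("empty matrix")
    m = matrix.table.to_numpy(dtype=np.int64)
    inter = m @ m.T
    sizes = m.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    j = inter / union
    np.fill_diagonal(j, 1.0)
    table = pd.DataFrame(j, index=matrix.row_ids, columns=matrix.row_ids)
    return SimilarityMatrix(table)


# ---------------------------------------------------------------------------
# deterministic agglomerative clustering (average linkage on 1 - J)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Merge:
    left: tuple    # sorted member ids of the left cluster
    right: tuple   # sorted member ids of the right cluster
    distance: float


def cluster_order(similarity: SimilarityMatrix):
    """Agglomerative clustering on distance 1 - J with average linkage.

    At each iteration the closest pair of clusters merges; ties are broken by
    the lexicographically smallest (representative, representative) id pair,
    so the result is deterministic and invariant to input row order.  Returns
    ``(leaf_order, merges)``: a leaf ordering for heat-map axes and the merge
    history.  With fewer than two rows the identity ordering is returned.
    """
    ids = sorted(str(i) for i in similarity.ids)
    if len(ids) < 2:
        return list(similarity.ids), []

    dist = {}
    sim = similarity.table
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            dist[(a, b)] = 1.0 - float(sim.loc[a, b])

    # cluster state: representative id -> (sorted member tuple, size)
    clusters = {a: ((a,), 1) for a in ids}
    merges: list[Merge] = []
    subtree: dict[str, list] = {a: [a] for a in ids}

    def pair_key(a, b):
        return (a, b) if a < b else (b, a)

    while len(clusters) > 1:
        reps = sorted(clusters)
        best = None
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                d = dist[pair_key(a, b)]
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        members_a, size_a = clusters.pop(a)
        members_b, size_b = clusters.pop(b)
        merges.append(Merge(members_a, members_b, d))
        new_rep = min(a, b)
        # Lance-Williams update for average linkage
        for other in clusters:
            da = dist.pop(pair_key(a, other))
            db = dist.pop(pair_key(b, other))
            dist[pair_key(new_rep, other)] = (
                (size_a * da + size_b * db) / (size_a + size_b))
        dist.pop(pair_key(a, b), None)
        clusters[new_rep] = (tuple(sorted(members_a + members_b)),
                             size_a + size_b)
        left, right = (a, b) if a < b else (b, a)
        subtree[new_rep] = [subtree[left], subtree[right]]

    def flatten(node, out):
        if isinstance(node, list):
            for child in node:
                flatten(child, out)
        else:
            out.append(node)

    leaf_order: list = []
    flatten(subtree[next(iter(clusters))], leaf_order)
    return leaf_order, merges
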