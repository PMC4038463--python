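"""On-disk dialects and validated in-memory records.

Every artifact the pipeline touches is a plain tab-separated table (or a
Newick tree).  An enzyme-mechanism dataset is three tables:

* ``entries.tsv``  — ``macie_id  ec_number  name``
* ``domains.tsv``  — ``macie_id  cath_id  is_catalytic`` (0/1)
* ``steps.tsv``    — ``macie_id  step_index  step_type  cath_id  role``

A reaction step carrying several annotations is written as repeated rows and
read back as a set.  CATH and EC codes are opaque dotted strings; only the EC
top-level class (first field) is ever interpreted downstream.

The 51-name mechanistic step-type vocabulary (the exact MACiE annotation
strings, e.g. "Proton transfer") ships with the package and is matched
case-sensitively; an alternative vocabulary file may be supplied wherever a
:class:`StepTypeVocabulary` is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from foldmech.tree import TreeNode, collapse_unifurcations

logger = logging.getLogger(__name__)

ROLES = ("Reactant", "Spectator")


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

class StepTypeVocabulary:
    """Ordered, duplicate-free list of mechanistic step-type names."""

    def __init__(self, names: Sequence[str]):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError("vocabulary contains duplicate step-type names")
        if not names:
            raise ValueError("vocabulary is empty")
        self.names = names
        self._index = {name: i for i, name in enumerate(names)}

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StepTypeVocabulary) and self.names == other.names

    def index(self, name: str) -> int:
        return self._index[name]

    @classmethod
    def from_file(cls, path) -> "StepTypeVocabulary":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls([ln for ln in lines if ln and not ln.startswith("#")])

    @classmethod
    def default(cls) -> "StepTypeVocabulary":
        """The packaged 51-name MACiE step-type vocabulary."""
        text = resources.files("foldmech.data").joinpath("step_types.txt").read_text()
        names = [ln.strip() for ln in text.splitlines()
                 if ln.strip() and not ln.startswith("#")]
        vocab = cls(names)
        if len(vocab) != 51:  # the shipped resource is versioned at 51 names
            raise RuntimeError("packaged step-type vocabulary is corrupted")
        return vocab


# ---------------------------------------------------------------------------
# enzyme-mechanism records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Participant:
    """A domain contributing residues to a reaction step, either chemically
    ('Reactant') or structurally ('Spectator')."""
    cath_id: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"invalid residue role {self.role!r}; "
                             f"expected one of {ROLES}")


@dataclass(frozen=True)
class DomainRef:
    cath_id: str
    is_catalytic: bool


@dataclass
class ReactionStep:
    """One step of a stepwise mechanism, with its annotation set."""
    step_index: int
    step_types: frozenset
    participants: tuple = ()

    def __post_init__(self):
        if self.step_index < 1:
            raise ValueError("step_index must be a positive integer")
        self.step_types = frozenset(self.step_types)
        if not self.step_types:
            raise ValueError("a reaction step needs at least one annotation")
        self.participants = tuple(self.participants)


@dataclass
class EnzymeEntry:
    """A MACiE-style record: one enzyme reaction, its domains and steps."""
    macie_id: str
    ec_number: str
    name: str
    domains: list = field(default_factory=list)
    steps: list = field(default_factory=list)

    @property
    def catalytic_domains(self) -> list:
        return [d for d in self.domains if d.is_catalytic]

    @property
    def ec_class(self) -> str:
        return self.ec_number.split(".", 1)[0]

    def validate(self, vocabulary: StepTypeVocabulary) -> None:
        cath_ids = {d.cath_id for d in self.domains}
        if len(cath_ids) != len(self.domains):
            raise ValueError(f"{self.macie_id}: duplicate domain cath_id")
        if not self.steps:
            raise ValueError(f"{self.macie_id}: entry has no reaction steps")
        for step in self.steps:
            unknown = step.step_types - set(vocabulary.names)
            if unknown:
                raise ValueError(
                    f"{self.macie_id} step {step.step_index}: unknown step "
                    f"type(s) {sorted(unknown)}")
            for part in step.participants:
                if part.cath_id not in cath_ids:
                    raise ValueError(
                        f"{self.macie_id} step {step.step_index}: participant "
                        f"cath_id {part.cath_id} absent from domains table")


def validate_entries(entries: Iterable[EnzymeEntry],
                     vocabulary: StepTypeVocabulary) -> None:
    seen = set()
    for entry in entries:
        if entry.macie_id in seen:
            raise ValueError(f"duplicate macie_id {entry.macie_id}")
        seen.add(entry.macie_id)
        entry.validate(vocabulary)


# ---------------------------------------------------------------------------
# abundance census
# ---------------------------------------------------------------------------

class AbundanceCensus:
    """Non-negative integer matrix of domain-structure occurrences, rows =
    structure (CATH) identifiers, columns = proteome identifiers."""

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.duplicated().any():
            dupes = table.index[table.index.duplicated()].tolist()
            raise ValueError(f"duplicate cath_id row label(s): {dupes}")
        if table.columns.duplicated().any():
            dupes = table.columns[table.columns.duplicated()].tolist()
            raise ValueError(f"duplicate proteome column label(s): {dupes}")
        values = table.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise ValueError(
                    f"non-integer abundance at row {table.index[bad[0]]!r}, "
                    f"column {table.columns[bad[1]]!r}")
            table = table.astype(np.int64)
            values = table.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at row {table.index[bad[0]]!r}, "
                f"column {table.columns[bad[1]]!r}")
        zero_rows = table.index[(values == 0).all(axis=1)]
        if len(zero_rows):
            raise ValueError(
                f"all-zero census row(s) for cath_id: {list(zero_rows)}")
        self.table = table

    @property
    def cath_ids(self) -> list:
        return list(self.table.index)

    @property
    def proteomes(self) -> list:
        return list(self.table.columns)

    @property
    def shape(self):
        return self.table.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceCensus):
            return NotImplemented
        return self.table.sort_index().sort_index(axis=1).equals(
            other.table.sort_index().sort_index(axis=1))


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def load_enzyme_dataset(entries_path, domains_path, steps_path,
                        vocabulary: StepTypeVocabulary) -> list:
    """Read the three-table enzyme-mechanism dialect into validated
    :class:`EnzymeEntry` records.

    Exact duplicate step rows are collapsed to a single annotation with a
    logged warning; a step row referencing a cath_id absent from the domains
    table, or an annotation outside the vocabulary, is an error.
    """
    entries_df = _read_tsv(entries_path, ["macie_id", "ec_number", "name"])
    domains_df = _read_tsv(domains_path, ["macie_id", "cath_id", "is_catalytic"])
    steps_df = _read_tsv(steps_path,
                         ["macie_id", "step_index", "step_type", "cath_id", "role"])

    n_dupes = int(steps_df.duplicated().sum())
    if n_dupes:
        logger.warning("steps table: collapsed %d duplicate row(s)", n_dupes)
        steps_df = steps_df.drop_duplicates()

    domains_by_entry: dict = {}
    for row in domains_df.itertuples(index=False):
        domains_by_entry.setdefault(row.macie_id, []).append(
            DomainRef(row.cath_id, bool(int(row.is_catalytic))))
    for refs in domains_by_entry.values():
        refs.sort(key=lambda d: d.cath_id)  # canonical: input order-insensitive

    # steps grouped (macie, index) -> {types}, {participants}
    steps_by_entry: dict = {}
    for row in steps_df.itertuples(index=False):
        if row.step_type not in vocabulary:
            raise ValueError(
                f"unknown step type {row.step_type!r} in steps table row "
                f"(macie_id={row.macie_id}, step_index={row.step_index})")
        key = (row.macie_id, int(row.step_index))
        types, parts = steps_by_entry.setdefault(row.macie_id, {}).setdefault(
            key, (set(), set()))
        types.add(row.step_type)
        if row.cath_id:
            parts.add(Participant(row.cath_id, row.role))

    entries: list = []
    for row in entries_df.itertuples(index=False):
        steps = [
            ReactionStep(idx, frozenset(types), tuple(sorted(
                parts, key=lambda p: (p.cath_id, p.role))))
            for (_, idx), (types, parts)
            in sorted(steps_by_entry.get(row.macie_id, {}).items())
        ]
        entries.append(EnzymeEntry(row.macie_id, row.ec_number, row.name,
                                   domains_by_entry.get(row.macie_id, []),
                                   steps))
    validate_entries(entries, vocabulary)
    return entries


def write_enzyme_dataset(entries: Sequence[EnzymeEntry], entries_path,
                         domains_path, steps_path) -> None:
    """Write the three-table dialect, rows sorted for byte-stable output."""
    ent = pd.DataFrame(
        [(e.macie_id, e.ec_number, e.name) for e in entries],
        columns=["macie_id", "ec_number", "name"]).sort_values("macie_id")
    dom = pd.DataFrame(
        [(e.macie_id, d.cath_id, int(d.is_catalytic))
         for e in entries for d in e.domains],
        columns=["macie_id", "cath_id", "is_catalytic"]).sort_values(
            ["macie_id", "cath_id"])
    step_rows = []
    for e in entries:
        for s in e.steps:
            participants = s.participants
            if not participants and e.domains:
                # single-domain entries may omit participants; make the row
                # explicit so the dialect round-trips
                participants = (Participant(e.domains[0].cath_id, "Reactant"),)
            for t in sorted(s.step_types):
                for p in participants:
                    step_rows.append((e.macie_id, s.step_index, t,
                                      p.cath_id, p.role))
    stp = pd.DataFrame(
        step_rows,
        columns=["macie_id", "step_index", "step_type", "cath_id", "role"]
    ).sort_values(["macie_id", "step_index", "step_type", "cath_id", "role"])
    ent.to_csv(entries_path, sep="\t", index=False)
    dom.to_csv(domains_path, sep="\t", index=False)
    stp.to_csv(steps_path, sep="\t", index=False)


def load_census(path) -> AbundanceCensus:
    """Read ``census.tsv`` (first column cath_id, one integer column per
    proteome) with strict validation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceCensus(df)


def write_census(census: AbundanceCensus, path) -> None:
    out = census.table.sort_index().sort_index(axis=1)
    out.index.name = "cath_id"
    out.to_csv(path, sep="\t")


def load_age_table(path):
    """Read ``ages.tsv`` (cath_id, nd) into an :class:`~foldmech.phylochronology.AgeTable`."""
    from foldmech.phylochronology import AgeTable

    df = _read_tsv(path, ["cath_id", "nd"])
    nd = pd.Series(df["nd"].astype(float).to_numpy(),
                   index=df["cath_id"].to_numpy(), name="nd")
    return AgeTable(nd)


def load_supplementary_dataset(path) -> pd.DataFrame:
    """Read a supplementary-style flat dataset: one row per (structure,
    enzyme) association with columns ``nd, cath_id, description, macie_id,
    ec_number, name`` (tab separated, header required)."""
    df = _read_tsv(path, ["nd", "cath_id", "macie_id", "ec_number"])
    df["nd"] = df["nd"].astype(float)
    if ((df["nd"] < 0) | (df["nd"] > 1)).any():
        raise ValueError("nd values must lie in [0, 1]")
    return df


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path) -> TreeNode:
    """Parse a rooted Newick tree with unique leaf labels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    root = _from_dendropy(dtree)
    labels = root.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf label(s): {dupes}")
    return root


def parse_newick(text: str) -> TreeNode:
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    root = _from_dendropy(dtree)
    labels = root.leaf_labels()
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf label(s): {dupes}")
    return root


def _from_dendropy(dtree: "dendropy.Tree") -> TreeNode:
    def convert(dnode):
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            return TreeNode(str(label))
        return TreeNode(children=[convert(c) for c in dnode.child_nodes()])

    return collapse_unifurcations(convert(dtree.seed_node))


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(tree.canonical_newick() + ";\n")


# ---------------------------------------------------------------------------
# analysis-table writer (deterministic, sorted)
# ---------------------------------------------------------------------------

def write_analysis_tables(obj, path) -> None:
    """Write any downstream analysis object as a sorted, tab-separated file.

    Dispatches on type: AgeTable, StructureStepMatrix, PatternTable,
    SimilarityMatrix and plain DataFrames are supported.  Output is stable
    across runs for identical input.
    """
    from foldmech.mapping import StructureStepMatrix
    from foldmech.patterns import PatternTable, SimilarityMatrix
    from foldmech.phylochronology import AgeTable

    if isinstance(obj, AgeTable):
        df = obj.to_frame().sort_index()
        df.index.name = "cath_id"
        df.to_csv(path, sep="\t")
    elif isinstance(obj, StructureStepMatrix):
        df = obj.table.astype(int)
        df = df.loc[sorted(df.index, key=lambda c: (obj.nd[c], c))]
        df.insert(0, "nd", obj.nd.reindex(df.index))
        df.index.name = "cath_id"
        df.to_csv(path, sep="\t")
    elif isinstance(obj, PatternTable):
        obj.to_frame().to_csv(path, sep="\t", index=False)
    elif isinstance(obj, SimilarityMatrix):
        df = obj.table.sort_index().sort_index(axis=1)
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.6f")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"no tabular writer for {type(obj).__name__}")
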