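"""Historical readouts: first appearances, the innovation table, the
cumulative discovery curve, and per-age summaries.

Ages are compared after rounding to 4 decimals, the precision at which
*nd* values are reported; this prevents floating-point noise from splitting
one fold age into two timeline columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from foldmech.io import EnzymeEntry
from foldmech.mapping import StructureStepMatrix

#: decimals at which two nd values are considered the same fold age
AGE_DECIMALS = 4


def _rounded_nd(matrix: StructureStepMatrix) -> pd.Series:
    return matrix.nd.round(AGE_DECIMALS)


def first_appearance(matrix: StructureStepMatrix) -> pd.Series:
    """Earliest fold age (minimum nd over possessing rows) per step type.

    Types present in no row are absent from the result.
    """
    if not len(matrix):
        raise ValueError("empty matrix")
    nd = _rounded_nd(matrix)
    table = matrix.table
    out = {}
    for step_type in table.columns:
        col = table[step_type]
        if col.any():
            out[step_type] = float(nd[col].min())
    return pd.Series(out, name="first_nd").sort_values(kind="mergesort")


@dataclass
class InnovationRecord:
    """One row of the innovation timeline: a structure at a fold age and the
    step types that no strictly older structure possesses."""
    nd: float
    row_id: str
    newly_introduced: frozenset


def innovation_table(matrix: StructureStepMatrix) -> list:
    """Credit each step type to every structure of the age at which the type
    first appears.

    Structures are processed in ascending nd (ties listed by row id); a type
    whose first age is *nd* appears in the ``newly_introduced`` set of every
    structure of that age possessing it.  Across all records the introduced
    sets are disjoint and their union is the set of types present.
    """
    if not len(matrix):
        raise ValueError("empty matrix")
    nd = _rounded_nd(matrix)
    first = first_appearance(matrix)
    records = []
    for row_id in sorted(matrix.row_ids, key=lambda r: (nd[r], str(r))):
        age = float(nd[row_id])
        types = matrix.row_types(row_id)
        new = frozenset(t for t in types if first[t] == age)
        # a type tied across several structures of one age is credited to
        # each of them, but counted once in coverage checks
        records.append(InnovationRecord(age, row_id, new))
    return records


def innovation_frame(records: Sequence[InnovationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.nd, r.row_id, ";".join(sorted(r.newly_introduced)))
         for r in records],
        columns=["nd", "row_id", "newly_introduced"])


def cumulative_curve(matrix: StructureStepMatrix,
                     vocabulary_size: Optional[int] = None) -> pd.DataFrame:
    """Proportion of the step-type vocabulary discovered by each fold age.

    One point per distinct nd; the fraction is the cumulative number of
    distinct types seen at or before that age over ``vocabulary_size``
    (defaults to the full vocabulary length of the matrix).
    """
    if not len(matrix):
        raise ValueError("empty matrix")
    if vocabulary_size is None:
        vocabulary_size = len(matrix.vocabulary)
    n_present = len(matrix.types_present)
    if vocabulary_size < n_present:
        raise ValueError("vocabulary_size smaller than the number of types present")
    first = first_appearance(matrix)
    counts = first.value_counts().sort_index()
    ages = sorted(_rounded_nd(matrix).unique())
    rows = []
    cum = 0
    for age in ages:
        cum += int(counts.get(age, 0))
        rows.append((float(age), cum, cum / vocabulary_size))
    return pd.DataFrame(rows, columns=["nd", "n_types", "fraction"])


def per_age_summary(culled: Sequence[EnzymeEntry],
                    matrix: StructureStepMatrix) -> pd.DataFrame:
    """Per distinct fold age: number of structures, number of enzyme entries,
    EC top-level classes present, and each structure's step-type count.

    A structure is counted at its own age.  A (multi-domain) enzyme entry is
    dated by its *oldest* catalytic domain with an age in the matrix; its EC
    class is tallied at that same age.
    """
    if not len(matrix):
        raise ValueError("empty matrix")
    nd = _rounded_nd(matrix)
    type_counts = matrix.table.sum(axis=1)

    by_age: dict = {}
    for row_id in matrix.row_ids:
        rec = by_age.setdefault(float(nd[row_id]), {
            "structures": [], "entries": [], "ec_classes": set()})
        rec["structures"].append((str(row_id), int(type_counts[row_id])))

    nd_lookup = matrix.nd  # unrounded per-row ages for entry dating
    for entry in culled:
        ages = [float(nd_lookup[d.cath_id]) for d in entry.catalytic_domains
                if d.cath_id in nd_lookup.index]
        if not ages:
            continue
        age = round(min(ages), AGE_DECIMALS)
        rec = by_age.setdefault(age, {"structures": [], "entries": [],
                                      "ec_classes": set()})
        rec["entries"].append(entry.macie_id)
        rec["ec_classes"].add(entry.ec_class)

    rows = []
    for age in sorted(by_age):
        rec = by_age[age]
        structures = sorted(rec["structures"])
        rows.append((
            age,
            len(structures),
            len(rec["entries"]),
            ";".join(sorted(rec["ec_classes"])),
            ";".join(s for s, _ in structures),
            ";".join(str(c) for _, c in structures),
        ))
    return pd.DataFrame(rows, columns=[
        "nd", "n_structures", "n_entries", "ec_classes",
        "structures", "type_counts"])
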