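"""Culling of enzyme-mechanism records and assignment of step types to aged
domain structures.

Two curation rules drive the mapping:

* only domains annotated as *catalytic* are retained, and an entry survives
  only if at least one of its catalytic domains has an age assignment;
* a step's annotations are credited to a structure only if the structure
  contributed at least one residue to that step, either as a "Reactant" or a
  "Spectator".  Single-domain enzymes need no participant bookkeeping: every
  step belongs to the lone catalytic domain.

Repeated use of an annotation within one enzyme counts once (presence, not
frequency), yielding a boolean structure x step-type matrix anchored to ages.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from foldmech.io import DomainRef, EnzymeEntry, StepTypeVocabulary
from foldmech.phylochronology import AgeTable

logger = logging.getLogger(__name__)

GRANULARITIES = ("structure", "enzyme-domain")


class StructureStepMatrix:
    """Boolean presence/absence matrix, rows = aged structures (or
    enzyme-domain pairs), columns = the full step-type vocabulary."""

    def __init__(self, table: pd.DataFrame, nd: pd.Series,
                 vocabulary: StepTypeVocabulary):
        if list(table.columns) != list(vocabulary.names):
            raise ValueError("matrix columns must equal the vocabulary, in order")
        if table.index.duplicated().any():
            raise ValueError("duplicate matrix row ids")
        table = table.astype(bool)
        if len(table) and not table.any(axis=1).all():
            empty = table.index[~table.any(axis=1)].tolist()
            raise ValueError(f"all-absent matrix row(s): {empty}")
        missing_age = [r for r in table.index if r not in nd.index]
        if missing_age:
            raise ValueError(f"matrix row(s) without an age: {missing_age}")
        self.table = table
        self.nd = nd.reindex(table.index).astype(float)
        self.vocabulary = vocabulary

    @property
    def row_ids(self) -> list:
        return list(self.table.index)

    def row_types(self, row_id) -> frozenset:
        row = self.table.loc[row_id]
        return frozenset(row.index[row])

    @property
    def types_present(self) -> frozenset:
        if not len(self.table):
            return frozenset()
        return frozenset(self.table.columns[self.table.any(axis=0)])

    def __len__(self) -> int:
        return len(self.table)


def cull_dataset(entries: Sequence[EnzymeEntry], age_table: AgeTable):
    """Apply the curation rules; never fails, always logs.

    Returns ``(culled_entries, exclusion_log)``.  In each surviving entry the
    non-catalytic domains (and catalytic domains without an age) are removed;
    entries left with no catalytic domain are excluded with reason
    ``no_catalytic_domain``, entries none of whose catalytic domains is aged
    with reason ``no_age``.  The log is a DataFrame with one row per exclusion
    or per-entry domain removal count.
    """
    culled: list[EnzymeEntry] = []
    log_rows = []
    for entry in entries:
        catalytic = [d for d in entry.domains if d.is_catalytic]
        n_noncat = len(entry.domains) - len(catalytic)
        if n_noncat:
            log_rows.append((entry.macie_id, "non_catalytic_domains_removed",
                             n_noncat))
        if not catalytic:
            log_rows.append((entry.macie_id, "excluded:no_catalytic_domain", 1))
            continue
        aged = [d for d in catalytic if d.cath_id in age_table]
        n_unaged = len(catalytic) - len(aged)
        if n_unaged:
            log_rows.append((entry.macie_id, "unaged_catalytic_domains_removed",
                             n_unaged))
        if not aged:
            log_rows.append((entry.macie_id, "excluded:no_age", 1))
            continue
        kept_ids = {d.cath_id for d in aged}
        new_steps = []
        for step in entry.steps:
            parts = tuple(p for p in step.participants if p.cath_id in kept_ids)
            new_steps.append(type(step)(step.step_index, step.step_types, parts))
        culled.append(EnzymeEntry(entry.macie_id, entry.ec_number, entry.name,
                                  [DomainRef(d.cath_id, True) for d in aged],
                                  new_steps))
    log = pd.DataFrame(log_rows, columns=["macie_id", "reason", "count"])
    n_excluded = int(log["reason"].str.startswith("excluded").sum()) if len(log) else 0
    logger.info("culling: %d entries in, %d retained, %d excluded",
                len(entries), len(culled), n_excluded)
    return culled, log


def build_pa_matrix(culled: Sequence[EnzymeEntry], age_table: AgeTable,
                    vocabulary: StepTypeVocabulary,
                    granularity: str = "structure") -> StructureStepMatrix:
    """Assign every step annotation to the responsible structures and
    aggregate to a boolean presence/absence matrix.

    ``granularity="structure"`` pools all enzymes using a structure into one
    row (the default repertoire view); ``"enzyme-domain"`` keeps one row per
    (enzyme, structure) pair, the per-enzyme view used when comparing pattern
    assignments across pathway members.

    Steps of a multi-domain enzyme that list no surviving participant cannot
    be attributed and are skipped with a log record (we do not guess).
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}")
    assignments: dict = {}

    def credit(entry, cath_id, types):
        row_id = (cath_id if granularity == "structure"
                  else f"{entry.macie_id}|{cath_id}")
        assignments.setdefault(row_id, (set(), cath_id))[0].update(types)

    n_skipped = 0
    for entry in culled:
        domains = entry.catalytic_domains
        if len(domains) == 1:
            lone = domains[0].cath_id
            for step in entry.steps:
                credit(entry, lone, step.step_types)
            continue
        for step in entry.steps:
            participant_ids = {p.cath_id for p in step.participants}
            if not participant_ids:
                n_skipped += 1
                logger.warning(
                    "unassignable: %s step %d has no participant records; "
                    "step skipped", entry.macie_id, step.step_index)
                continue
            for cath_id in participant_ids:
                credit(entry, cath_id, step.step_types)
    if n_skipped:
        logger.info("skipped %d unassignable step(s)", n_skipped)

    row_ids = sorted(assignments)
    data = np.zeros((len(row_ids), len(vocabulary)), dtype=bool)
    nd_vals = {}
    for i, row_id in enumerate(row_ids):
        types, cath_id = assignments[row_id]
        for t in types:
            data[i, vocabulary.index(t)] = True
        nd_vals[row_id] = float(age_table.nd[cath_id])
    table = pd.DataFrame(data, index=row_ids, columns=list(vocabulary.names))
    nd = pd.Series(nd_vals, dtype=float, name="nd")
    if not len(table):
        table = pd.DataFrame(np.zeros((0, len(vocabulary)), dtype=bool),
                             columns=list(vocabulary.names))
        nd = pd.Series(dtype=float, name="nd")
    return StructureStepMatrix(table, nd, vocabulary)
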