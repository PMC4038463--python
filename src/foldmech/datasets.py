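"""Bundled desk-scale datasets.

Two curated fixtures ship with the package so that the whole pipeline can be
exercised without any download:

* the **curated timeline** — 26 CATH H-level structures with published
  relative ages (*nd*) and the mechanistic step types first recorded for
  each, including the 20-type repertoire of the class I aldolase TIM-barrel
  superfamily (CATH 3.20.20.70);
* the **purine pathway** — the enzymes of the nucleotide-interconversion
  subnetwork of purine metabolism with their aged structures and per-
  structure step-type sets, the classic showcase of early recruitment of the
  "Proton transfer" + "Bimolecular nucleophilic substitution" combination.

Both are returned as validated :class:`~foldmech.io.EnzymeEntry` lists plus
an :class:`~foldmech.phylochronology.AgeTable`, ready for the culling,
mapping, timeline and pattern stages.  Entries of the curated timeline are
synthetic single-domain wrappers (ids ``E0001`` ...) around the curated
(structure, age, type) associations; the purine fixture keeps its original
enzyme identifiers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from foldmech.io import (DomainRef, EnzymeEntry, Participant, ReactionStep,
                         StepTypeVocabulary, validate_entries)
from foldmech.phylochronology import AgeTable

ALDOLASE_CATH = "3.20.20.70"


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("foldmech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def curated_timeline(vocabulary: StepTypeVocabulary | None = None):
    """The curated structure-age timeline.

    Returns ``(entries, age_table, descriptions)`` where ``entries`` holds
    one synthetic single-domain enzyme per structure carrying that
    structure's full step-type set, ``age_table`` maps the 26 structures to
    their published nd values, and ``descriptions`` maps cath_id to the
    structure's name.
    """
    vocabulary = vocabulary or StepTypeVocabulary.default()
    df = _data_frame("curated_timeline.tsv")
    descriptions = dict(zip(df["cath_id"], df["description"]))
    entries = []
    nd = {}
    for i, (cath, group) in enumerate(df.groupby("cath_id", sort=True)):
        nd[cath] = float(group["nd"].iloc[0])
        types = sorted(set(group["step_type"]))
        steps = [ReactionStep(j + 1, frozenset([t]),
                              (Participant(cath, "Reactant"),))
                 for j, t in enumerate(types)]
        entries.append(EnzymeEntry(
            f"E{i + 1:04d}", "0.0.0.0", descriptions[cath],
            [DomainRef(cath, True)], steps))
    validate_entries(entries, vocabulary)
    age_table = AgeTable(pd.Series(nd, name="nd"))
    return entries, age_table, descriptions


def purine_pathway(vocabulary: StepTypeVocabulary | None = None):
    """The purine nucleotide-interconversion fixture.

    Returns ``(entries, age_table)``.  The two-structure pyruvate kinase
    record is a genuine multi-domain entry whose steps list both structures
    as participants, exercising the participant-based assignment rule.
    """
    vocabulary = vocabulary or StepTypeVocabulary.default()
    df = _data_frame("purine_pathway.tsv")
    nd = {}
    by_entry: dict = {}
    for row in df.itertuples(index=False):
        nd[row.cath_id] = float(row.nd)
        rec = by_entry.setdefault(row.macie_id, {
            "name": row.name, "ec": row.ec_number, "types_by_cath": {}})
        rec["types_by_cath"].setdefault(row.cath_id, []).append(row.step_type)

    entries = []
    for macie_id in sorted(by_entry):
        rec = by_entry[macie_id]
        caths = sorted(rec["types_by_cath"])
        domains = [DomainRef(c, True) for c in caths]
        steps = []
        idx = 1
        for cath in caths:
            for t in rec["types_by_cath"][cath]:
                steps.append(ReactionStep(idx, frozenset([t]),
                                          (Participant(cath, "Reactant"),)))
                idx += 1
        entries.append(EnzymeEntry(macie_id, rec["ec"], rec["name"],
                                   domains, steps))
    validate_entries(entries, vocabulary)
    return entries, AgeTable(pd.Series(nd, name="nd"))
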