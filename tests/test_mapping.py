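import pandas as pd
import pytest

from foldmech import simulate as sim
from foldmech.io import DomainRef, EnzymeEntry, Participant, ReactionStep
from foldmech.mapping import build_pa_matrix, cull_dataset
from foldmech.phylochronology import AgeTable


def entry(macie_id, domains, steps, ec="1.1.1.1", name="enzyme"):
    return EnzymeEntry(macie_id, ec, name, domains, steps)


def step(idx, types, parts=()):
    return ReactionStep(idx, frozenset(types),
                        tuple(Participant(c, r) for c, r in parts))


@pytest.fixture
def ages():
    return AgeTable(pd.Series({
        "1.20.210.10": 0.30, "3.40.50.1580": 0.235,
        "3.40.50.300": 0.0, "3.40.50.1980": 0.401,
        "9.99.99.99": 0.5}))


class TestCulling:
    def test_many_domains_one_catalytic(self, ages):
        """A cytochrome-c-oxidase-like record: 16 annotated domains, one
        catalytic; the entry survives with exactly that domain."""
        domains = [DomainRef(f"2.10.{i}.10", False) for i in range(15)]
        domains.append(DomainRef("1.20.210.10", True))
        e = entry("M0124", domains, [step(1, {"Electron transfer"},
                                          [("1.20.210.10", "Reactant")])],
                  ec="1.9.3.1")
        culled, log = cull_dataset([e], ages)
        assert len(culled) == 1
        assert [d.cath_id for d in culled[0].domains] == ["1.20.210.10"]
        assert (log["reason"] == "non_catalytic_domains_removed").any()

    def test_entry_with_unaged_catalytic_domain_excluded(self, ages):
        e = entry("M9999", [DomainRef("8.88.88.88", True)],
                  [step(1, {"Redox"}, [("8.88.88.88", "Reactant")])])
        culled, log = cull_dataset([e], ages)
        assert culled == []
        assert (log["reason"] == "excluded:no_age").any()

    def test_entry_with_no_catalytic_domain_excluded(self, ages):
        e = entry("M9998", [DomainRef("1.20.210.10", False)],
                  [step(1, {"Redox"})])
        culled, log = cull_dataset([e], ages)
        assert culled == []
        assert (log["reason"] == "excluded:no_catalytic_domain").any()

    def test_fully_catalytic_aged_dataset_passes_unchanged(self, ages):
        e = entry("M0001", [DomainRef("3.40.50.300", True)],
                  [step(1, {"Proton transfer"}, [("3.40.50.300", "Reactant")])])
        culled, log = cull_dataset([e], ages)
        assert culled == [e]
        assert log.empty


class TestBuildMatrix:
    def test_single_domain_enzyme_pools_repeated_types(self, ages,
                                                       vocabulary):
        """Purine-nucleoside-phosphorylase-like record: four steps with a
        repeated 'Proton transfer' collapse to three distinct types."""
        cath = "3.40.50.1580"
        e = entry("M0017", [DomainRef(cath, True)], [
            step(1, {"Proton transfer"}),
            step(2, {"Heterolysis"}),
            step(3, {"Bimolecular nucleophilic addition"}),
            step(4, {"Proton transfer"}),
        ], ec="2.4.2.1")
        matrix = build_pa_matrix([e], ages, vocabulary)
        assert matrix.row_types(cath) == frozenset({
            "Proton transfer", "Heterolysis",
            "Bimolecular nucleophilic addition"})

    def test_multidomain_assignment_follows_participants(self, ages,
                                                         vocabulary):
        """Nitrogenase-like record: the ancient core carries the first two
        steps, the younger domain the remaining thirteen."""
        core, late = "3.40.50.300", "3.40.50.1980"
        steps = [
            step(1, {"Bimolecular nucleophilic substitution",
                     "Electron transfer"}, [(core, "Reactant")]),
            step(2, {"Proton transfer"}, [(core, "Spectator")]),
        ]
        for i in range(3, 16):
            steps.append(step(i, {"Proton transfer", "Electron transfer"},
                              [(late, "Reactant")]))
        e = entry("M0212", [DomainRef(core, True), DomainRef(late, True)],
                  steps, ec="1.18.6.1")
        matrix = build_pa_matrix([e], ages, vocabulary)
        assert matrix.row_types(core) == frozenset({
            "Bimolecular nucleophilic substitution", "Electron transfer",
            "Proton transfer"})
        assert matrix.row_types(late) == frozenset({
            "Proton transfer", "Electron transfer"})

    def test_spectator_participation_suffices(self, ages, vocabulary):
        a, b = "3.40.50.300", "3.40.50.1980"
        e = entry("M0002", [DomainRef(a, True), DomainRef(b, True)],
                  [step(1, {"Redox"}, [(a, "Spectator")])])
        matrix = build_pa_matrix([e], ages, vocabulary)
        assert matrix.row_types(a) == frozenset({"Redox"})
        assert b not in matrix.row_ids

    def test_unassignable_step_skipped_and_logged(self, ages, vocabulary,
                                                  caplog):
        a, b = "3.40.50.300", "3.40.50.1980"
        e = entry("M0003", [DomainRef(a, True), DomainRef(b, True)],
                  [step(1, {"Redox"}, [(a, "Reactant")]),
                   step(2, {"Coordination"})])  # no participants
        with caplog.at_level("WARNING"):
            matrix = build_pa_matrix([e], ages, vocabulary)
        assert "Coordination" not in matrix.types_present
        assert any("unassignable" in r.message for r in caplog.records)

    def test_empty_input_gives_empty_matrix(self, ages, vocabulary):
        matrix = build_pa_matrix([], ages, vocabulary)
        assert len(matrix) == 0

    def test_enzyme_domain_granularity_keeps_one_row_per_pair(self, purine,
                                                              vocabulary):
        entries, ages = purine
        culled, _ = cull_dataset(entries, ages)
        matrix = build_pa_matrix(culled, ages, vocabulary,
                                 granularity="enzyme-domain")
        assert "M0326|3.20.20.60" in matrix.row_ids
        assert "M0326|2.40.33.10" in matrix.row_ids
        assert len(matrix) == 7  # one row per (enzyme, structure) pair

    def test_assignment_never_invents_usage(self, vocabulary):
        """Every true (structure, type) cell is witnessed by a culled entry
        that uses the type in a step the structure participates in (or whose
        lone catalytic domain is the structure)."""
        ages_sim = AgeTable(pd.Series(
            {f"C{i}": i / 9 for i in range(10)}))
        entries, _ = sim.simulate_enzymes(ages_sim, vocabulary,
                                          n_enzymes=40, seed=8)
        culled, _ = cull_dataset(entries, ages_sim)
        matrix = build_pa_matrix(culled, ages_sim, vocabulary)

        witnessed = set()
        for e in culled:
            domains = e.catalytic_domains
            for s in e.steps:
                carriers = ({domains[0].cath_id} if len(domains) == 1
                            else {p.cath_id for p in s.participants})
                for c in carriers:
                    for t in s.step_types:
                        witnessed.add((c, t))
        for rid in matrix.row_ids:
            for t in matrix.row_types(rid):
                assert (rid, t) in witnessed

    def test_permuting_entries_leaves_matrix_unchanged(self, purine,
                                                       vocabulary):
        entries, ages = purine
        culled, _ = cull_dataset(entries, ages)
        m1 = build_pa_matrix(culled, ages, vocabulary)
        m2 = build_pa_matrix(list(reversed(culled)), ages, vocabulary)
        assert m1.table.equals(m2.table)
        assert m1.nd.equals(m2.nd)

    def test_matrix_matches_generator_ground_truth(self, vocabulary):
        """Oracle equivalence: assignments recover exactly the generator's
        (structure, step type) usage pairs."""
        ages_sim = AgeTable(pd.Series({f"C{i}": i / 14 for i in range(15)}))
        entries, truth = sim.simulate_enzymes(ages_sim, vocabulary,
                                              n_enzymes=60, seed=4)
        culled, _ = cull_dataset(entries, ages_sim)
        matrix = build_pa_matrix(culled, ages_sim, vocabulary)
        observed = {(rid, t) for rid in matrix.row_ids
                    for t in matrix.row_types(rid)}
        assert observed == truth.usage_pairs
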