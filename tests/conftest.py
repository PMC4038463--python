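import numpy as np
import pandas as pd
import pytest

from foldmech.io import StepTypeVocabulary
from foldmech.mapping import StructureStepMatrix
from foldmech import datasets


@pytest.fixture(scope="session")
def vocabulary():
    return StepTypeVocabulary.default()


@pytest.fixture(scope="session")
def curated(vocabulary):
    """(entries, age_table, descriptions) of the bundled structure timeline."""
    return datasets.curated_timeline(vocabulary)


@pytest.fixture(scope="session")
def curated_matrix(vocabulary, curated):
    from foldmech.mapping import build_pa_matrix, cull_dataset

    entries, ages, _ = curated
    culled, _ = cull_dataset(entries, ages)
    return build_pa_matrix(culled, ages, vocabulary)


@pytest.fixture(scope="session")
def purine(vocabulary):
    return datasets.purine_pathway(vocabulary)


@pytest.fixture
def make_matrix(vocabulary):
    """Build a StructureStepMatrix from {row_id: set_of_types} and ages."""

    def build(rows, nd=None):
        ids = sorted(rows)
        data = pd.DataFrame(False, index=ids, columns=list(vocabulary.names))
        for rid, types in rows.items():
            for t in types:
                data.loc[rid, t] = True
        if nd is None:
            nd = {rid: i / max(len(ids) - 1, 1) for i, rid in enumerate(ids)}
        return StructureStepMatrix(data, pd.Series(nd, dtype=float), vocabulary)

    return build


@pytest.fixture
def random_bool_matrix(vocabulary):
    """Random nonempty-row boolean matrix as a StructureStepMatrix."""

    def build(n_rows, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((n_rows, len(vocabulary))) < 0.15
        for i in range(n_rows):
            if not data[i].any():
                data[i, rng.integers(len(vocabulary))] = True
        ids = [f"R{i:03d}" for i in range(n_rows)]
        nd = pd.Series(np.round(rng.random(n_rows), 4), index=ids)
        table = pd.DataFrame(data, index=ids, columns=list(vocabulary.names))
        return StructureStepMatrix(table, nd, vocabulary)

    return build
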