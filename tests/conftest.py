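import numpy as np
import pytest

from lipidquant.annotate import ResolutionModel, build_overlap_groups, match_features
from lipidquant.chem import default_database
from lipidquant.isocorrect import correct_feature_table
from lipidquant.quantify import normalize
from lipidquant.simulate import StudyConfig, simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def study(db):
    """One default control-vs-patient study (fixed seed)."""
    return simulate_study(StudyConfig(), seed=STUDY_SEED, db=db)


@pytest.fixture(scope="session")
def processed(db, study):
    """The study run through annotate -> correct -> normalize."""
    table, truth = study
    ann = match_features(table, db)
    groups = build_overlap_groups(
        ann, db, ResolutionModel(), features=table.features
    )
    corrected, diag, unknowns = correct_feature_table(table, groups, ann)
    abundance = normalize(corrected, db, table.samples)
    return {
        "table": table,
        "truth": truth,
        "annotations": ann,
        "groups": groups,
        "corrected": corrected,
        "diagnostics": diag,
        "unknowns": unknowns,
        "abundance": abundance,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
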