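import numpy as np
import pytest
from rdkit import Chem

from cpdrift import ScoreModelSpec
from cpdrift.synthetic import DriftScenario, generate, molecule_fixtures


@pytest.fixture(scope="session")
def centroid_spec():
    """Fast distance-based score model used throughout the unit tests."""
    return ScoreModelSpec(algorithm="centroid")


@pytest.fixture(scope="session")
def small_batches():
    """Exchangeable three-batch dataset, small enough for fast tests."""
    return generate(
        DriftScenario(n_train=600, n_test=600, n_score=600, d=20, seed=11)
    )


@pytest.fixture(scope="session")
def drifted_batches():
    """Same shape but with a strong covariate shift in test/score."""
    return generate(
        DriftScenario(
            n_train=600, n_test=600, n_score=600, d=20, seed=11, drift_delta=3.0
        )
    )


@pytest.fixture(scope="session")
def fixture_mols():
    """Parseable fixture molecules as RDKit Mols (unparseable entry skipped)."""
    mols = []
    for smi, _ in molecule_fixtures():
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            mols.append(mol)
    return mols


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
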