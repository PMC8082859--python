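"""Synthetic drifted three-batch datasets and molecule fixtures.

Emulates the chronological train / test / score release pattern of public
toxicity screening data: three batches of binary-labelled feature vectors
with Tox21-like class imbalance, where the later two batches may have
drifted away from the training batch.

The generative model is a pair of class-conditional multivariate Gaussians
with isotropic noise.  Drift is a covariate shift: all class-conditional
means of the *test* and *score* batches are translated by ``drift_delta``
noise standard deviations.  By default the translation runs along the
inactive-to-active class axis, the minimal shift that is actually visible
to a margin-based nonconformity score (a translation orthogonal to the
class-discriminant axis leaves per-class score differences, and hence the
conformal layer, essentially unchanged).  A user-supplied direction and a
label-flip drift mode are available for robustness experiments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse

__all__ = ["DriftScenario", "Batch", "DriftBatches", "generate", "molecule_fixtures"]


@dataclass(frozen=True)
class DriftScenario:
    """Parameters of a three-batch drifted binary classification dataset.

    Parameters
    ----------
    n_train, n_test, n_score:
        Examples per batch.
    d:
        Feature dimension.
    active_fraction:
        Expected fraction of actives (label 1) in every batch; the default
        0.1 mirrors the strong imbalance of in vitro toxicity endpoints.
    class_sep:
        Distance between the active and inactive class means, in noise
        standard deviations.
    drift_delta:
        Translation applied to all class-conditional means of the test and
        score batches, in noise standard deviations.  0 means all three
        batches are exchangeable.
    noise_sd:
        Isotropic within-class standard deviation.
    drift_mode:
        "covariate" translates the means; "label_flip" leaves features in
        place and flips each label with probability
        ``drift_delta / (1 + drift_delta)`` in the drifted batches.
    drift_direction:
        Optional unit-vector override for the covariate-shift direction.
    seed:
        Seed for all randomness in the generator.
    """

    n_train: int = 2000
    n_test: int = 2000
    n_score: int = 2000
    d: int = 50
    active_fraction: float = 0.1
    class_sep: float = 3.0
    drift_delta: float = 0.0
    noise_sd: float = 1.0
    drift_mode: Literal["covariate", "label_flip"] = "covariate"
    drift_direction: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.active_fraction < 1.0:
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.drift_delta < 0:
            raise ValueError("drift_delta must be nonnegative")


@dataclass
class Batch:
    """A labelled feature batch."""

    X: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class DriftBatches:
    train: Batch
    test: Batch
    score: Batch


def _sample_batch(
    rng: np.random.Generator,
    n: int,
    mu0: np.ndarray,
    mu1: np.ndarray,
    active_fraction: float,
    noise_sd: float,
) -> Batch:
    y = (rng.random(n) < active_fraction).astype(np.int64)
    if y.sum() < 2 or (n - y.sum()) < 2:
        raise ValueError(
            f"batch of size {n} with active_fraction {active_fraction} drew "
            "fewer than 2 examples of one class; increase n"
        )
    X = rng.normal(scale=noise_sd, size=(n, len(mu0)))
    X[y == 0] += mu0
    X[y == 1] += mu1
    return Batch(X=X, y=y)


def generate(scenario: DriftScenario) -> DriftBatches:
    """Draw the three batches described by ``scenario``.

    Returns train, test and score batches; with ``drift_delta == 0`` the
    three are exchangeable, otherwise test and score share the drifted
    distribution.  Bit-reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    d = scenario.d

    # class axis: fixed random unit direction drawn before any sampling
    axis = rng.normal(size=d)
    axis /= np.linalg.norm(axis)
    mu0 = np.zeros(d)
    mu1 = scenario.class_sep * scenario.noise_sd * axis

    if scenario.drift_direction is not None:
        direction = np.asarray(scenario.drift_direction, dtype=float)
        if direction.shape != (d,):
            raise ValueError("drift_direction must have length d")
        direction = direction / np.linalg.norm(direction)
    else:
        direction = axis

    shift = scenario.drift_delta * scenario.noise_sd * direction
    covariate = scenario.drift_mode == "covariate"

    train = _sample_batch(
        rng, scenario.n_train, mu0, mu1, scenario.active_fraction, scenario.noise_sd
    )
    drifted = []
    for n in (scenario.n_test, scenario.n_score):
        if covariate:
            batch = _sample_batch(
                rng, n, mu0 + shift, mu1 + shift, scenario.active_fraction, scenario.noise_sd
            )
        else:
            batch = _sample_batch(
                rng, n, mu0, mu1, scenario.active_fraction, scenario.noise_sd
            )
            flip_p = scenario.drift_delta / (1.0 + scenario.drift_delta)
            flips = rng.random(n) < flip_p
            batch.y = np.where(flips, 1 - batch.y, batch.y)
        drifted.append(batch)
    return DriftBatches(train=train, test=drifted[0], score=drifted[1])


def generate_sparse_counts(scenario: DriftScenario) -> DriftBatches:
    """Sparse nonnegative-count variant of :func:`generate`.

    Produces Poisson count features whose per-class rates are a softplus of
    the Gaussian means used by :func:`generate`; used in integration tests
    with the fingerprint-matrix reader, where real descriptors are sparse
    counts.  Returned ``X`` attributes are ``scipy.sparse.csr_matrix``.
    """
    dense = generate(scenario)
    rng = np.random.default_rng(scenario.seed + 1)

    def _to_counts(batch: Batch) -> Batch:
        rates = np.log1p(np.exp(batch.X - 2.0))  # softplus, mostly ~0
        counts = rng.poisson(rates)
        return Batch(X=sparse.csr_matrix(counts), y=batch.y)

    return DriftBatches(
        train=_to_counts(dense.train),
        test=_to_counts(dense.test),
        score=_to_counts(dense.score),
    )


# Fixed molecule fixtures: (SMILES, label).  The list deliberately contains a
# salt, charged species, an agreeing and a conflicting duplicate pair, a
# too-small molecule, an inorganic salt and benzene, so every preprocessing
# branch and the descriptor symmetry checks are exercised.
_MOLECULE_FIXTURES: tuple[tuple[str, int], ...] = (
    ("c1ccccc1", 0),                     # benzene: 6 symmetry-equivalent atoms
    ("CCC", 0),                          # propane: 3 heavy atoms, too small
    ("CC(=O)[O-].[Na+]", 0),             # sodium acetate: salt + neutralisation
    ("[Na+].[Cl-]", 0),                  # rock salt: no organic fragment
    ("CC(=O)Oc1ccccc1C(=O)O", 0),        # aspirin
    ("CC(=O)Oc1ccccc1C(=O)O", 0),        # aspirin duplicate, agreeing label
    ("CN1C=NC2=C1C(=O)N(C)C(=O)N2C", 1), # caffeine
    ("CN1C=NC2=C1C(=O)N(C)C(=O)N2C.Cl", 0),  # caffeine HCl: conflicts after strip
    ("C[N+](C)(C)C", 0),                 # tetramethylammonium: non-neutralisable
    ("CC[NH3+]", 0),                     # ethylammonium: neutralisable cation
    ("c1ccc(cc1)[O-]", 1),               # phenolate: neutralisable anion
    ("OCC(O)C(O)C(O)C(O)CO", 0),         # sorbitol
    ("Clc1ccccc1Cl", 1),                 # 1,2-dichlorobenzene
    ("CCOC(=O)c1ccccc1", 0),             # ethyl benzoate
    ("Nc1ccc(cc1)S(=O)(=O)N", 1),        # sulfanilamide
    ("CC(C)Cc1ccc(cc1)C(C)C(=O)O", 0),   # ibuprofen
    ("Oc1ccc(Cl)cc1", 1),                # 4-chlorophenol
    ("C1CCOC1", 0),                      # THF
    ("O=C(O)c1ccccc1", 0),               # benzoic acid
    ("O=C([O-])c1ccccc1.[K+]", 0),       # potassium benzoate: agrees after strip
    ("N#Cc1ccccc1", 1),                  # benzonitrile
    ("CSc1ccccc1", 0),                   # thioanisole
    ("O=[N+]([O-])c1ccccc1", 1),         # nitrobenzene: charges kept as-is
    ("FC(F)(F)c1ccccc1", 0),             # benzotrifluoride
    ("C1CC1", 0),                        # cyclopropane: exactly 3 heavy atoms
    ("CC(N)=O", 0),                      # acetamide: 4 heavy atoms, boundary
    ("c1ccc2ccccc2c1", 1),               # naphthalene
    ("CC(=O)Nc1ccc(O)cc1", 0),           # paracetamol
    ("invalid_smiles", 0),               # unparseable entry
    ("[Mg+2].[O-]S([O-])(=O)=O", 0),     # magnesium sulfate: inorganic
)


def molecule_fixtures() -> list[tuple[str, int]]:
    """Frozen list of small (SMILES, label) fixtures for pipeline tests."""
    return list(_MOLECULE_FIXTURES)


def molecule_fixtures_checksum() -> str:
    """SHA-256 over the fixture list; guards accidental edits."""
    payload = "\n".join(f"{s}\t{l}" for s, l in _MOLECULE_FIXTURES)
    return hashlib.sha256(payload.encode()).hexdigest()
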