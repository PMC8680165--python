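import numpy as np
import pytest

from pharmspace import (
    ReferenceBasis,
    PharmacogenomicModel,
    TrainConfig,
    generate_panel,
)


@pytest.fixture(scope="session")
def tiny_panel():
    """Small noiseless latent-factor panel shared by fast tests."""
    return generate_panel(n_lines=20, n_drugs=4, n_genes=100, f_true=2,
                          sigma_response=0.0, missing_rate=0.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_toy_model(f=1, n_drugs=2, W_P=None, Q=None, b_Q=None, o=None):
    """A hand-built model over a 2-line reference whose fold-change columns
    are exact negations, so a query equal to either line has kernel (+-1, -+1)."""
    gene_ids = ["g0", "g1", "g2"]
    fc = np.array([[1.0, -1.0], [-2.0, 2.0], [1.0, -1.0]])
    basis = ReferenceBasis(gene_ids, np.zeros(3), gene_ids, ["R1", "R2"], fc)
    if W_P is None:
        W_P = np.array([[1.0], [0.0]]) if f == 1 else np.zeros((2, f))
    if Q is None:
        Q = np.zeros((n_drugs, f))
    if b_Q is None:
        b_Q = np.zeros(n_drugs)
    if o is None:
        o = np.zeros(n_drugs)
    drug_ids = [f"D{i}" for i in range(n_drugs)]
    return PharmacogenomicModel(f=f, W_P=np.asarray(W_P, float), Q=np.asarray(Q, float),
                                b_Q=np.asarray(b_Q, float), drug_ids=drug_ids,
                                basis=basis, max_dose_log2=np.asarray(o, float),
                                config=TrainConfig(f=f))


@pytest.fixture
def toy_model_factory():
    return make_toy_model
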