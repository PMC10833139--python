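import numpy as np
import pytest

from mvintegrate import (
    MultiViewData,
    Outcome,
    cv_selpcca,
    fit_sida,
    generate_selp_data,
    generate_sida_data,
)


@pytest.fixture(scope="session")
def selp_small():
    """Small two-view latent-factor dataset with strong signal."""
    data, truth = generate_selp_data(n=300, p1=30, p2=30, s1=5, s2=5,
                                     sigma2=0.25, seed=11)
    return data, truth


@pytest.fixture(scope="session")
def selpcca_model(selp_small):
    data, _ = selp_small
    return cv_selpcca(data, ncancorr=2, seed=11)


@pytest.fixture(scope="session")
def sida_small():
    data, truth = generate_sida_data(n_per_class=80, K=2, D=2, p=[30, 30],
                                     s=[8, 8], delta=2.828, psi=0.5,
                                     sigma2=0.25, seed=21)
    return data, truth


@pytest.fixture(scope="session")
def sida_model(sida_small):
    data, _ = sida_small
    return fit_sida(data, seed=21)


def make_mvdata(X1, X2, y=None, kind="binary"):
    n = X1.shape[0]
    outcome = Outcome(kind, values=np.asarray(y)) if y is not None else None
    return MultiViewData(
        views=[np.asarray(X1, float), np.asarray(X2, float)],
        view_names=["view1", "view2"],
        feature_names=[[f"a{j}" for j in range(X1.shape[1])],
                       [f"b{j}" for j in range(X2.shape[1])]],
        sample_ids=[f"S{i}" for i in range(n)],
        outcome=outcome,
    )
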