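from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from chillgm import load_dataset

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def beef():
    return load_dataset("beef")


@pytest.fixture(scope="session")
def pork():
    return load_dataset("pork")


@pytest.fixture(scope="session")
def seasonal():
    return load_dataset("seasonal")


def reference_matrix(name: str) -> pd.DataFrame:
    """Frozen reference matrices for the bundled surveillance datasets."""
    return pd.read_csv(DATA_DIR / f"ref_{name}.csv", index_col=0)


def random_correlation(rng, p: int) -> np.ndarray:
    """A random well-conditioned correlation matrix (Wishart-based)."""
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def logdet_oracle_fit(R: np.ndarray, zero_pairs: set) -> np.ndarray:
    """Independent constrained-MLE oracle for covariance selection.

    Maximizes the Gaussian log-likelihood log det K - tr(R K) directly over
    the free entries of the precision matrix K (entries in ``zero_pairs``
    are held at zero) with a quasi-Newton solver, then returns K^-1.  Shares
    no code with the iterative-proportional-scaling implementation.
    """
    p = len(R)
    free = [(i, i) for i in range(p)] + [
        (i, j) for i in range(p) for j in range(i + 1, p)
        if (i, j) not in zero_pairs and (j, i) not in zero_pairs
    ]

    def build(theta):
        K = np.zeros((p, p))
        for t, (i, j) in zip(theta, free):
            K[i, j] = K[j, i] = t
        return K

    def negll(theta):
        K = build(theta)
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e10
        return -2.0 * np.log(np.diag(L)).sum() + np.trace(R @ K)

    def grad(theta):
        K = build(theta)
        G = -np.linalg.inv(K) + R
        return np.array([G[i, j] * (1 if i == j else 2) for (i, j) in free])

    x0 = np.array([1.0 if i == j else 0.0 for (i, j) in free])
    res = minimize(negll, x0, jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    return np.linalg.inv(build(res.x))
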