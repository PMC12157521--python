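import numpy as np
import pandas as pd
import pytest

from knockblock.genotype_io import GenotypeMatrix


def random_correlation(p: int, rng: np.random.Generator, jitter: float = 1.0) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    A = rng.standard_normal((p, p))
    sigma = A @ A.T + jitter * p * np.eye(p)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def matrix_with_correlation(sigma: np.ndarray, n: int | None = None) -> np.ndarray:
    """An n x p matrix whose empirical X'X/n equals sigma exactly.

    Uses X = sqrt(n) * L' with L the Cholesky factor, padded with zero rows.
    """
    p = sigma.shape[0]
    n = n or p
    if n < p:
        raise ValueError("need n >= p")
    L = np.linalg.cholesky(sigma)
    X = np.zeros((n, p))
    X[:p, :] = np.sqrt(n) * L.T
    return X


def make_genotypes(
    values: np.ndarray, chrom: str = "1", spacing: int = 1000
) -> GenotypeMatrix:
    values = np.asarray(values, dtype=np.float64)
    n, p = values.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(p, dtype=np.int64) + 1) * spacing,
            "id": [f"v{j}" for j in range(p)],
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeMatrix(
        values=values, samples=[f"s{i}" for i in range(n)], variants=variants
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
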