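from __future__ import annotations

import numpy as np
import pytest

from lcintensity import MatrixSeries, TransitionMatrix, simple_scheme

ABC = ["A", "B", "C"]


@pytest.fixture
def scheme_abc():
    return simple_scheme(ABC)


@pytest.fixture
def m_star() -> TransitionMatrix:
    """Worked 3-category fixture: ΔY=5, total 300 km², gross change 35."""
    return TransitionMatrix(
        [[75, 15, 10], [5, 90, 5], [0, 0, 100]], ABC, 1985, 1990, "ALL"
    )


@pytest.fixture
def m_second() -> TransitionMatrix:
    """Companion 2-year interval: total 300 km², gross change 18."""
    return TransitionMatrix(
        [[90, 5, 5], [4, 92, 4], [0, 0, 100]], ABC, 1990, 1992, "ALL"
    )


@pytest.fixture
def series_two(scheme_abc, m_star, m_second) -> MatrixSeries:
    return MatrixSeries.from_matrices(scheme_abc, [m_star, m_second])


def random_matrix(
    rng: np.random.Generator,
    n_cat: int = 4,
    from_year: int = 2000,
    duration: int = 5,
    stratum: str = "ALL",
    labels: list[str] | None = None,
    sparsity: float = 0.0,
) -> TransitionMatrix:
    """Random non-negative area matrix with a dominant diagonal."""
    if labels is None:
        labels = [chr(ord("A") + k) for k in range(n_cat)]
    vals = rng.gamma(1.0, 10.0, size=(n_cat, n_cat))
    vals[np.eye(n_cat, dtype=bool)] += rng.gamma(5.0, 100.0, size=n_cat)
    if sparsity > 0:  # off-diagonal only, so total area stays positive
        mask = (rng.random((n_cat, n_cat)) < sparsity) & ~np.eye(n_cat, dtype=bool)
        vals[mask] = 0.0
    return TransitionMatrix(vals, labels, from_year, from_year + duration, stratum)
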