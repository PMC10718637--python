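import numpy as np
import pytest

from audiogene.audiometry import (
    Audiogram,
    ClassificationRules,
    Ear,
    NoiseHistory,
    Participant,
    ProfileBasis,
    Sex,
)

FREQS = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)


@pytest.fixture(scope="session")
def basis() -> ProfileBasis:
    return ProfileBasis()


@pytest.fixture(scope="session")
def rules() -> ClassificationRules:
    return ClassificationRules()


def make_audiogram(pid: str, ear: Ear, values) -> Audiogram:
    return Audiogram(pid, ear, dict(zip(FREQS, values)))


def make_participant(pid: str, sex: Sex, left_vals, right_vals,
                     age: float = 70.0) -> Participant:
    return Participant(
        pid, sex, age, NoiseHistory.NEGATIVE,
        make_audiogram(pid, Ear.LEFT, left_vals),
        make_audiogram(pid, Ear.RIGHT, right_vals),
    )


def grid_search_fit(freqs, values, basis: ProfileBasis, step: float = 0.1,
                    lo: float = 0.0, hi: float = 120.0):
    """Brute-force (m, s) grid search minimising the sum of squared residuals.

    Independent oracle for the non-negative component fit: evaluates the
    quadratic SSE surface on a regular grid at ``step`` dB resolution.
    """
    A = basis.at(freqs)
    values = np.asarray(values, dtype=float)
    t1, t2 = A[:, 0] @ values, A[:, 1] @ values
    a11, a22, a12 = A[:, 0] @ A[:, 0], A[:, 1] @ A[:, 1], A[:, 0] @ A[:, 1]
    grid = np.arange(lo, hi + step / 2, step)
    M = grid[:, None]
    S = grid[None, :]
    sse = M**2 * a11 + 2 * M * S * a12 + S**2 * a22 - 2 * M * t1 - 2 * S * t2
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(grid[i]), float(grid[j])
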