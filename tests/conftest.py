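import numpy as np
import pytest

from ecsdiff import (
    AGAROSE_VISCOSITY,
    CONSTANTS,
    SolutionModel,
    generate_rve,
)


@pytest.fixture(scope="session")
def constants():
    return CONSTANTS


@pytest.fixture(scope="session")
def solution_if():
    return SolutionModel()


@pytest.fixture(scope="session")
def solution_agarose():
    return SolutionModel(mu=AGAROSE_VISCOSITY)


@pytest.fixture(scope="session")
def small_geometry():
    """A 6 um packed cross-section (fast to audit exhaustively)."""
    return generate_rve(domain_size=6.0, seed=7, restarts=40)


@pytest.fixture(scope="session")
def wm_geom():
    """The study's standard 18 um white-matter RVE with a release pocket."""
    return generate_rve(seed=1, clear_radius=0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_audit(geometry, tol=1e-9):
    """Independent O(n^2) oracle: explicit loops, no shared code paths."""
    L = geometry.domain_size
    centers = np.asarray(geometry.centers)
    radii = np.asarray(geometry.radii)
    n = len(radii)
    violations = []
    for i in range(n):
        x, y, r = centers[i, 0], centers[i, 1], radii[i]
        if r <= 0:
            violations.append(("radius", i))
        if x - r < -tol or x + r > L + tol or y - r < -tol or y + r > L + tol:
            violations.append(("boundary", i))
        for j in range(i + 1, n):
            dx = centers[j, 0] - x
            dy = centers[j, 1] - y
            gap = (dx * dx + dy * dy) ** 0.5 - r - radii[j]
            if gap < geometry.min_gap - tol:
                violations.append(("gap", i, j, gap))
    return violations
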