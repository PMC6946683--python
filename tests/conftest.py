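import numpy as np
import pytest

import glycomesh as gm


@pytest.fixture(scope="session")
def small_network():
    """54-tip default-parameter network used across morphometry tests."""
    params = gm.GeneratorParams()
    return gm.generate_network(params, seed=3, n_tips=54)


@pytest.fixture(scope="session")
def calibrated_mesh():
    """Mesh-calibrated params and recorded ground-truth pore size.

    Session-scoped: the calibration runs large networks and is shared by
    every test that needs the calibrated conditions.
    """
    params, ground_truth = gm.calibrate_mesh(29.0)
    return params, ground_truth


@pytest.fixture(scope="session")
def lc_pattern():
    """Liquid-crystalline termini pattern at the reported 32 nm spacing."""
    return gm.generate_termini_pattern(
        "liquid_crystal", 32.0, 4.0, ((0.0, 1200.0), (0.0, 1200.0)), seed=7
    )


def brute_force_nn_mean(points: np.ndarray) -> float:
    """All-pairs nearest-neighbor oracle (no spatial index)."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def brute_force_pair_histogram(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """All-pairs distance histogram oracle for RDF peak location."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(points), k=1)
    counts, _ = np.histogram(d[iu], bins=edges)
    return counts
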