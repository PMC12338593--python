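import numpy as np
import pytest

from neuroparti.synthetic_data import generate_vertices, sample_population


@pytest.fixture(scope="session")
def triangle_vertices():
    """A fixed, well-separated triangle in 2-D."""
    return np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.8]])


@pytest.fixture(scope="session")
def simplex_population():
    """n=900, D=19, k=3 population with 2% noise — the standard study scale."""
    vertices = generate_vertices(3, 19, min_separation=1.0, seed=11)
    diff = vertices[:, None] - vertices[None]
    diameter = np.sqrt((diff**2).sum(-1)).max()
    table, truth = sample_population(
        3, 19, 900, dirichlet_alpha=1.0, noise_sd=0.02 * diameter,
        seed=42, vertices=vertices)
    return table, truth


def matched_vertex_errors(true_vertices, fitted_vertices):
    """Distances between true and fitted vertices under optimal matching."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    cost = cdist(true_vertices, fitted_vertices)
    r, c = linear_sum_assignment(cost)
    return cost[r, c]
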