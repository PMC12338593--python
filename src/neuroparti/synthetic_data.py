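"""Simplex-structured synthetic populations with known ground truth.

The generative model mirrors the Pareto trade-off picture: a population of
``n`` individuals, each described by ``D`` trait coordinates that are noisy
convex combinations of ``k`` extreme "archetypes".  Mixture weights are drawn
from a Dirichlet distribution (single concentration parameter controlling how
strongly individuals specialize), measurement noise is isotropic Gaussian in
the ambient trait space, confounds contaminate the compositions linearly, and
behavioral features can be planted whose level decays with distance from a
chosen archetype.  A "clinical" subgroup is generated by biasing the Dirichlet
concentration toward one archetype so its mass shifts without leaving the
simplex.

Everything is seeded and returns a :class:`SyntheticTruth` record so that
downstream recovery can be scored against the exact generating quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .compositions import CompositionTable, ConfoundTable

__all__ = [
    "SyntheticTruth",
    "generate_vertices",
    "sample_population",
    "plant_feature",
    "add_confounds",
    "generate_null_population",
    "generate_component_maps",
    "generate_clinical_subgroup",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated population.

    vertices : (k, D) true archetype positions.
    weights : (n, k) Dirichlet mixture weights, rows sum to 1.
    noise_sd : ambient Gaussian noise standard deviation.
    planted_effects : list of (feature_id, archetype_index, direction, effect_size).
    confound_betas : (C, D) linear contamination coefficients, or None.
    seed : root seed used for generation.
    """

    vertices: np.ndarray
    weights: np.ndarray
    noise_sd: float
    planted_effects: list = field(default_factory=list)
    confound_betas: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        k, d = self.vertices.shape
        if k < 2:
            raise ValueError("need at least 2 archetypes")
        if d < k - 1:
            raise ValueError(f"a {k}-vertex simplex needs ambient dimension >= {k - 1}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        sums = self.weights.sum(axis=1)
        if self.weights.size and not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("mixture weight rows must sum to 1")

    @property
    def k(self) -> int:
        return self.vertices.shape[0]

    @property
    def d(self) -> int:
        return self.vertices.shape[1]

    def simplex_diameter(self) -> float:
        """Largest pairwise distance between true archetypes."""
        diff = self.vertices[:, None, :] - self.vertices[None, :, :]
        return float(np.sqrt((diff**2).sum(-1)).max())


def generate_vertices(
    k: int,
    d: int,
    min_separation: float = 1.0,
    seed: int | None = None,
    on_simplex: bool = False,
    max_retries: int = 500,
) -> np.ndarray:
    """Draw ``k`` archetype positions in ``d`` dimensions, pairwise well separated.

    With ``on_simplex=True`` the vertices are themselves compositions (rows on
    the probability simplex), which is the natural regime for variance
    proportions; otherwise they are Gaussian draws at a scale set by
    ``min_separation``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if d < k - 1:
        raise ValueError(f"a {k}-vertex simplex needs d >= {k - 1}, got d={d}")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        if on_simplex:
            V = rng.dirichlet(np.full(d, 0.5), size=k)
        else:
            V = rng.normal(scale=1.5 * min_separation, size=(k, d))
        diff = V[:, None, :] - V[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_separation:
            return V
    raise RuntimeError(
        f"could not place {k} vertices with separation {min_separation} "
        f"in {d} dimensions after {max_retries} attempts"
    )


def sample_population(
    k: int,
    d: int,
    n: int,
    dirichlet_alpha: float | np.ndarray = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    vertices: np.ndarray | None = None,
    on_simplex: bool = False,
    min_separation: float = 1.0,
) -> tuple[CompositionTable, SyntheticTruth]:
    """Sample ``n`` individuals as noisy convex combinations of archetypes.

    Each sample is ``weights @ vertices`` plus isotropic Gaussian noise with
    standard deviation ``noise_sd`` applied per coordinate in the ambient
    space.  The Dirichlet concentration ``dirichlet_alpha`` (scalar for the
    symmetric case, or length-``k`` vector) sets how strongly individuals
    concentrate near archetypes (small alpha) or near the centroid (large).
    """
    if n < k:
        raise ValueError(f"need at least n={k} samples for a {k}-archetype fit, got {n}")
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,)).copy()
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    if vertices is None:
        vertices = generate_vertices(
            k, d, min_separation=min_separation,
            seed=rng.integers(2**31), on_simplex=on_simplex,
        )
    else:
        vertices = np.asarray(vertices, dtype=float)
        if vertices.shape != (k, d):
            raise ValueError(f"vertices must be {(k, d)}, got {vertices.shape}")
    weights = rng.dirichlet(alpha, size=n)
    X = weights @ vertices
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    table = CompositionTable(
        subject_ids=[f"s{i:04d}" for i in range(n)],
        component_ids=[f"IC{j + 1:02d}" for j in range(d)],
        values=X,
    )
    truth = SyntheticTruth(
        vertices=vertices, weights=weights, noise_sd=float(noise_sd), seed=seed
    )
    return table, truth


def _normalized_vertex_distance(X: np.ndarray, vertex: np.ndarray) -> np.ndarray:
    dist = np.sqrt(((X - vertex[None, :]) ** 2).sum(axis=1))
    dmax = dist.max()
    return dist / dmax if dmax > 0 else dist


def plant_feature(
    X: np.ndarray,
    truth: SyntheticTruth,
    archetype_index: int,
    direction: str = "max",
    effect_size: float = 1.0,
    noise_sd: float = 0.0,
    kind: str = "continuous",
    seed: int | None = None,
    base_rate: float = 0.3,
    feature_id: str | None = None,
) -> np.ndarray:
    """Create a feature whose level tracks proximity to one archetype.

    Continuous features follow the Pareto reading that task performance decays
    with distance from the specialized archetype:
    ``feature = sign * effect_size * (1 - d_norm) + noise`` where ``d_norm``
    is the distance to the chosen vertex scaled to [0, 1] and ``sign`` is +1
    for ``direction='max'`` (feature largest near the archetype) and -1 for
    ``'min'``.  Boolean features are Bernoulli draws whose success probability
    is monotone decreasing (max) or increasing (min) in the distance via a
    logistic link around ``base_rate``.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    if not 0 <= archetype_index < truth.k:
        raise ValueError(f"archetype_index {archetype_index} out of range")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    rng = np.random.default_rng(seed)
    d_norm = _normalized_vertex_distance(np.asarray(X, float), truth.vertices[archetype_index])
    sign = 1.0 if direction == "max" else -1.0
    if kind == "continuous":
        feature = sign * effect_size * (1.0 - d_norm)
        if noise_sd > 0:
            feature = feature + rng.normal(scale=noise_sd, size=feature.shape)
        elif effect_size == 0:
            # pure-noise null even when noise_sd defaulted to 0
            feature = rng.normal(size=feature.shape)
    elif kind == "boolean":
        from scipy.special import expit, logit

        eta = logit(base_rate) + sign * effect_size * (0.5 - d_norm)
        p = expit(eta)
        feature = (rng.random(size=p.shape) < p).astype(float)
    else:
        raise ValueError("kind must be 'continuous' or 'boolean'")
    truth.planted_effects.append(
        (feature_id or f"planted_{len(truth.planted_effects)}",
         archetype_index, direction, float(effect_size))
    )
    return feature


def add_confounds(
    comp: CompositionTable,
    conf: ConfoundTable,
    betas: np.ndarray,
    truth: SyntheticTruth | None = None,
) -> CompositionTable:
    """Contaminate compositions with a linear confound signal.

    ``output = input + confounds @ betas``, clipped at zero and re-normalized
    per row, so the contaminated table remains a valid composition while a
    linear, regression-recoverable signal is embedded.  ``betas`` has shape
    (n_confounds, n_components).
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (len(conf.confound_ids), len(comp.component_ids)):
        raise ValueError(
            f"betas must be {(len(conf.confound_ids), len(comp.component_ids))}, "
            f"got {betas.shape}"
        )
    if list(comp.subject_ids) != list(conf.subject_ids):
        raise ValueError("subject ids of composition and confound tables do not match")
    contaminated = comp.values + conf.values @ betas
    contaminated = np.clip(contaminated, 0.0, None)
    sums = contaminated.sum(axis=1)
    if np.any(sums <= 0):
        raise ValueError("confound contamination zeroed out entire rows")
    contaminated = contaminated / sums[:, None]
    if truth is not None:
        truth.confound_betas = betas
    return CompositionTable(list(comp.subject_ids), list(comp.component_ids), contaminated)


def generate_null_population(
    n: int,
    d: int,
    covariance: np.ndarray | float = 1.0,
    seed: int | None = None,
) -> CompositionTable:
    """Multivariate Gaussian ellipsoid with no simplex structure.

    Used to calibrate the t-ratio test: elliptical clouds should not look
    simplex-like more often than chance.  ``covariance`` may be a scalar
    (isotropic), a length-``d`` vector of variances, or a full ``(d, d)``
    covariance matrix.
    """
    if n <= d:
        raise ValueError("need n > d for a non-degenerate Gaussian cloud")
    rng = np.random.default_rng(seed)
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim == 0:
        X = rng.normal(scale=np.sqrt(cov), size=(n, d))
    elif cov.ndim == 1:
        X = rng.normal(size=(n, d)) * np.sqrt(cov)[None, :]
    else:
        X = rng.multivariate_normal(np.zeros(d), cov, size=n)
    return CompositionTable(
        subject_ids=[f"s{i:04d}" for i in range(n)],
        component_ids=[f"IC{j + 1:02d}" for j in range(d)],
        values=X,
    )


def generate_component_maps(
    n_components: int,
    grid_shape: tuple[int, int, int] = (10, 10, 10),
    smoothness_scale: float = 2.0,
    seed: int | None = None,
):
    """Spatially smooth component maps on a 3-D lattice.

    Each map is white Gaussian noise filtered with a Gaussian kernel of width
    ``smoothness_scale`` (lattice units), standing in for ICA spatial
    component maps.  Returns a :class:`~neuroparti.archetype_maps.ComponentMaps`
    with voxel coordinates on the integer lattice.
    """
    from .archetype_maps import ComponentMaps

    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid_shape entries must be positive")
    rng = np.random.default_rng(seed)
    maps = np.empty((int(np.prod(grid_shape)), n_components))
    for j in range(n_components):
        vol = rng.normal(size=grid_shape)
        if smoothness_scale > 0:
            vol = ndimage.gaussian_filter(vol, sigma=smoothness_scale, mode="wrap")
            vol = (vol - vol.mean()) / vol.std()
        maps[:, j] = vol.ravel()
    coords = np.stack(
        np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    return ComponentMaps(
        values=maps,
        coords=coords,
        grid_shape=grid_shape,
        component_ids=[f"IC{j + 1:02d}" for j in range(n_components)],
    )


def generate_clinical_subgroup(
    truth: SyntheticTruth,
    target_archetype: int,
    shift_fraction: float,
    n: int,
    noise_sd: float | None = None,
    seed: int | None = None,
    base_alpha: float = 1.0,
) -> tuple[CompositionTable, SyntheticTruth]:
    """Sample a subgroup whose mass is shifted toward one archetype.

    The subgroup uses the same archetypes as ``truth`` but an asymmetric
    Dirichlet whose target-archetype expected weight is moved from the
    symmetric 1/k toward 1 by ``shift_fraction``:
    ``E[w_target] = 1/k + shift_fraction * (1 - 1/k)``.  ``shift_fraction=0``
    reproduces the symmetric base population distribution.
    """
    if not 0 <= shift_fraction <= 1:
        raise ValueError("shift_fraction must lie in [0, 1]")
    k = truth.k
    if not 0 <= target_archetype < k:
        raise ValueError("target_archetype out of range")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    target_mean = 1.0 / k + shift_fraction * (1.0 - 1.0 / k)
    if target_mean >= 1.0:
        target_mean = 1.0 - 1e-9
    alpha = np.full(k, base_alpha)
    # alpha_t / (alpha_t + (k-1) base) = target_mean
    alpha[target_archetype] = (k - 1) * base_alpha * target_mean / (1.0 - target_mean)
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(alpha, size=n)
    X = weights @ truth.vertices
    if noise_sd > 0:
        X = X + rng.normal(scale=noise_sd, size=X.shape)
    table = CompositionTable(
        subject_ids=[f"c{i:04d}" for i in range(n)],
        component_ids=[f"IC{j + 1:02d}" for j in range(truth.d)],
        values=X,
    )
    sub_truth = SyntheticTruth(
        vertices=truth.vertices.copy(), weights=weights,
        noise_sd=float(noise_sd), seed=seed,
    )
    return table, sub_truth
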