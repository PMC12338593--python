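"""Minimum-volume simplex (archetype) fitting and its significance test.

The Pareto task inference pipeline treats each subject's adjusted variance
composition as a point in trait space.  After centering PCA (no
standardization) and projection onto the first ``k - 1`` principal
components, a ``k``-vertex simplex of (locally) minimal volume approximately
enclosing the point cloud is found with a SISAL-style solver: working with
the inverse of the lifted vertex matrix, the negative log-determinant
(log-volume) is minimized plus a hinge penalty on negative barycentric
coordinates, so a tunable number of outliers may sit outside the simplex.

Significance of the fitted polytope is assessed with the t-ratio test: the
ratio of the convex-hull volume of the scores to the simplex volume is close
to 1 when the data genuinely fill a simplex, and the observed ratio is
compared against ratios from datasets whose columns were independently
permuted (destroying the dependence structure while preserving marginals).
Vertex uncertainty is quantified by bootstrap resampling with label
alignment by optimal assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist

__all__ = [
    "PCAModel",
    "ArchetypeSolution",
    "BootstrapResult",
    "TRatioResult",
    "SimplexFitError",
    "fit_pca",
    "fit_simplex",
    "fit_archetypes",
    "convex_hull_volume",
    "simplex_volume",
    "t_ratio_test",
    "bootstrap_archetypes",
    "reconstruct_full_space",
    "distances_to_archetypes",
]


class SimplexFitError(RuntimeError):
    """Raised when the minimum-volume simplex solver fails to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class PCAModel:
    """Centered (unstandardized) PCA basis.

    ``loadings`` is ``(D, m)`` with orthonormal columns; ``mean`` the column
    means used for centering; ``explained_variance`` the per-component sample
    variances of the scores (non-increasing).
    """

    mean: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self.mean + np.asarray(scores, float) @ self.loadings.T


@dataclass
class ArchetypeSolution:
    """A fitted k-vertex simplex in PC space and in the original space."""

    k: int
    vertices_pc: np.ndarray            # (k, k-1)
    vertices_full: np.ndarray | None   # (k, D) once reconstructed
    t_ratio: float | None = None
    p_value: float | None = None
    diagnostics: dict = field(default_factory=dict)


@dataclass
class BootstrapResult:
    """Aligned bootstrap vertex clouds and per-vertex covariances."""

    n_boot: int
    clouds: np.ndarray        # (n_ok, k, m)
    covariances: np.ndarray   # (k, m, m)
    means: np.ndarray         # (k, m)
    n_skipped: int = 0


@dataclass
class TRatioResult:
    t_obs: float
    t_null: np.ndarray
    p_value: float
    n_shuffles: int


def fit_pca(X: np.ndarray, m: int) -> tuple[PCAModel, np.ndarray]:
    """Centered PCA without standardization.

    Returns the model and the ``(n, m)`` score matrix.  The sign of each
    loading is fixed so its largest-magnitude entry is positive, removing the
    sign indeterminacy of the SVD.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if m > min(n - 1, d):
        raise ValueError(f"m={m} exceeds the maximal rank {min(n - 1, d)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(n, d) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if m > rank:
        raise ValueError(f"m={m} exceeds rank {rank} of the centered data")
    loadings = Vt[:m].T
    # sign convention: largest-|.| entry of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(m)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    explained = (s[:m] ** 2) / (n - 1)
    return PCAModel(mean=mean, loadings=loadings, explained_variance=explained), scores


def _furthest_point_init(Y: np.ndarray, k: int, inflate: float = 1.1) -> np.ndarray:
    """Greedy furthest-point k vertices, inflated about their centroid."""
    centroid = Y.mean(axis=0)
    idx = [int(np.argmax(((Y - centroid) ** 2).sum(axis=1)))]
    for _ in range(k - 1):
        d2 = np.min(cdist(Y, Y[idx]) ** 2, axis=1)
        idx.append(int(np.argmax(d2)))
    V = Y[idx].copy()
    c = V.mean(axis=0)
    return c + inflate * (V - c)


def _smooth_hinge(v: np.ndarray, delta: float) -> tuple[float, np.ndarray]:
    """Huberized hinge max(0, v): value sum and elementwise derivative."""
    out = np.zeros_like(v)
    grad = np.zeros_like(v)
    mid = (v > 0) & (v <= delta)
    hi = v > delta
    out[mid] = v[mid] ** 2 / (2 * delta)
    grad[mid] = v[mid] / delta
    out[hi] = v[hi] - delta / 2
    grad[hi] = 1.0
    return float(out.sum()), grad


def fit_simplex(
    scores: np.ndarray,
    k: int,
    penalty: float = 0.1,
    max_iter: int = 400,
    seed: int | None = None,
    delta: float = 1e-7,
    n_restarts: int = 3,
) -> ArchetypeSolution:
    """Fit a minimum-volume k-vertex simplex approximately enclosing scores.

    SISAL-style formulation: with lifted data ``Y~ = [y; 1]`` and the inverse
    lifted vertex matrix ``Q``, minimize ``-log|det Q| + penalty * sum
    hinge(-(Q Y~))`` subject to the affine constraint that barycentric
    coordinates sum to one (eliminated analytically).  The hinge penalty is
    per unit barycentric depth per point, so larger values force harder
    enclosure.  Initialization is a furthest-point simplex inflated by 10%;
    the seed only enters through jittered restarts after a failed solve.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be 2-D")
    n, m = Y.shape
    if m < k - 1:
        raise ValueError(f"k={k} archetypes need scores of dimension >= {k - 1}, got {m}")
    if n < k:
        raise ValueError(f"need at least {k} points to fit a {k}-vertex simplex")
    Y = Y[:, : k - 1]
    m = k - 1

    # scale-normalize for conditioning; vertices are rescaled on exit
    scale = float(np.sqrt((Y**2).sum(axis=1).mean()))
    if scale <= 0:
        raise SimplexFitError("degenerate (all-zero) score cloud")
    Ys = Y / scale
    Yt = np.vstack([Ys.T, np.ones((1, n))])  # (k, n)

    e_last = np.zeros(k)
    e_last[-1] = 1.0

    def unpack(p: np.ndarray) -> np.ndarray:
        P = p.reshape(k - 1, k)
        return np.vstack([P, (e_last - P.sum(axis=0))[None, :]])

    def objective(p: np.ndarray, width: float = delta):
        Q = unpack(p)
        sign, logabs = np.linalg.slogdet(Q)
        if sign == 0 or not np.isfinite(logabs):
            return 1e12, np.zeros_like(p)
        A = Q @ Yt
        hval, hgrad = _smooth_hinge(-A, width)
        f = -logabs + penalty * hval
        gQ = -np.linalg.inv(Q).T - penalty * (hgrad @ Yt.T)
        gP = gQ[: k - 1] - gQ[-1][None, :]
        return f, gP.ravel()

    rng = np.random.default_rng(seed)
    V0 = _furthest_point_init(Ys, k)
    last_res = None
    for attempt in range(n_restarts):
        M0 = np.vstack([V0.T, np.ones((1, k))])
        try:
            Q0 = np.linalg.inv(M0)
        except np.linalg.LinAlgError:
            V0 = V0 + rng.normal(scale=0.05, size=V0.shape)
            continue
        # coarse solve with a wider smoothing band, then polish at the target
        # width; the polish starts near the optimum and converges quickly
        res = minimize(
            objective, Q0[: k - 1].ravel(), jac=True, method="L-BFGS-B",
            args=(max(delta, 1e-3),),
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7, "maxls": 60},
        )
        if delta < 1e-3 and np.all(np.isfinite(res.x)):
            res2 = minimize(
                objective, res.x, jac=True, method="L-BFGS-B", args=(delta,),
                options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-8,
                         "maxls": 60},
            )
            if np.isfinite(res2.fun):
                res2.nit += res.nit
                res = res2
        last_res = res
        Q = unpack(res.x)
        sign, logabs = np.linalg.slogdet(Q)
        if np.isfinite(res.fun) and sign != 0 and res.status in (0, 1):
            M = np.linalg.inv(Q)
            vertices = M[: k - 1].T * scale  # (k, m)
            A = Q @ Yt
            frac_outside = float((A.min(axis=0) < -1e-6).mean())
            diag = {
                "iterations": int(res.nit),
                "converged": bool(res.status == 0),
                "objective": float(res.fun),
                "penalty": penalty,
                "seed": seed,
                "frac_outside": frac_outside,
                "restarts": attempt,
            }
            if res.status == 1 and res.nit >= max_iter:
                raise SimplexFitError(
                    f"simplex solver did not converge in {max_iter} iterations", diag
                )
            return ArchetypeSolution(
                k=k, vertices_pc=vertices, vertices_full=None, diagnostics=diag
            )
        # jitter and retry
        V0 = _furthest_point_init(Ys, k) + rng.normal(scale=0.05 * (attempt + 1), size=(k, m))
    diag = {"status": getattr(last_res, "status", None),
            "message": getattr(last_res, "message", "no successful solve")}
    raise SimplexFitError("minimum-volume simplex fit failed", diag)


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume (length/area for 1-D/2-D) of the convex hull of the points."""
    points = np.asarray(points, dtype=float)
    n, m = points.shape
    if n < m + 1:
        raise ValueError(f"need at least {m + 1} points in {m} dimensions")
    if m == 1:
        vol = float(points.max() - points.min())
        if vol <= 0:
            raise ValueError("degenerate (zero-length) hull")
        return vol
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(f"degenerate convex hull: {exc}") from exc
    if hull.volume <= 0:
        raise ValueError("degenerate (zero-volume) hull")
    return float(hull.volume)


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume of a k-vertex simplex in (k-1) dimensions: |det(V_2-V_1, ...)|/(k-1)!."""
    V = np.asarray(vertices, dtype=float)
    k = V.shape[0]
    if V.shape[1] != k - 1:
        raise ValueError(f"{k} vertices must live in {k - 1} dimensions")
    edges = V[1:] - V[0]
    det = np.linalg.det(edges)
    vol = abs(det) / np.prod(np.arange(1, k))
    if vol <= 0 or not np.isfinite(vol):
        raise ValueError("degenerate simplex (affinely dependent vertices)")
    return float(vol)


def fit_archetypes(
    X_adjusted: np.ndarray,
    k: int,
    penalty: float = 0.1,
    max_iter: int = 400,
    seed: int | None = None,
    delta: float = 1e-7,
) -> tuple[PCAModel, np.ndarray, ArchetypeSolution]:
    """PCA to k-1 components, simplex fit, t-ratio and full-space vertices."""
    pca, scores = fit_pca(X_adjusted, k - 1)
    sol = fit_simplex(scores, k, penalty=penalty, max_iter=max_iter, seed=seed,
                      delta=delta)
    sol.vertices_full = reconstruct_full_space(sol, pca)
    sol.t_ratio = convex_hull_volume(scores) / simplex_volume(sol.vertices_pc)
    return pca, scores, sol


def _column_shuffle(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute every column (preserves marginals)."""
    idx = np.argsort(rng.random(X.shape), axis=0)
    return X[idx, np.arange(X.shape[1])[None, :]]


def t_ratio_test(
    X_adjusted: np.ndarray,
    k: int,
    n_shuffles: int = 1000,
    seed: int | None = None,
    penalty: float = 5.0,
    max_iter: int = 400,
    delta: float = 1e-3,
) -> TRatioResult:
    """Permutation test for simplex-like structure.

    ``t = hull_volume / simplex_volume`` on the (k-1)-dimensional scores;
    values near 1 indicate that the data nearly fill their minimal enclosing
    simplex.  Each null dataset permutes every column of the adjusted matrix
    independently and is re-fit from scratch (PCA + simplex).  The empirical
    p-value is ``(1 + #{t_null >= t_obs}) / (1 + n_shuffles)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    X = np.asarray(X_adjusted, dtype=float)
    rng = np.random.default_rng(seed)
    _, _, sol = fit_archetypes(X, k, penalty=penalty, max_iter=max_iter,
                               seed=int(rng.integers(2**31)), delta=delta)
    t_obs = sol.t_ratio
    t_null = np.empty(n_shuffles)
    failures = 0
    max_failures = max(1, int(0.01 * n_shuffles))
    i = 0
    while i < n_shuffles:
        Xn = _column_shuffle(X, rng)
        try:
            _, _, sol_n = fit_archetypes(Xn, k, penalty=penalty, max_iter=max_iter,
                                         seed=int(rng.integers(2**31)), delta=delta)
        except (SimplexFitError, ValueError):
            failures += 1
            if failures > max_failures:
                raise SimplexFitError(
                    f"more than {max_failures} null re-fits failed "
                    f"({failures}/{n_shuffles})"
                )
            continue
        t_null[i] = sol_n.t_ratio
        i += 1
    p = (1 + int((t_null >= t_obs).sum())) / (1 + n_shuffles)
    return TRatioResult(t_obs=float(t_obs), t_null=t_null, p_value=float(p),
                        n_shuffles=n_shuffles)


def _align_vertices(reference: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Permute vertices to minimize total distance to the reference set."""
    cost = cdist(reference, vertices)
    _, col = linear_sum_assignment(cost)
    return vertices[col]


def bootstrap_archetypes(
    X_adjusted: np.ndarray,
    k: int,
    n_boot: int = 1000,
    seed: int | None = None,
    penalty: float = 0.1,
    max_iter: int = 400,
    reference: ArchetypeSolution | None = None,
    pca: PCAModel | None = None,
    delta: float = 1e-3,
) -> BootstrapResult:
    """Bootstrap vertex uncertainty with label alignment.

    Each draw resamples subjects with replacement, projects the resample onto
    the reference PC basis, and re-fits the simplex; the resulting vertices
    are matched to the reference solution by the permutation minimizing total
    Euclidean distance (resolving label switching).  Degenerate resamples are
    skipped; more than 5% skips is an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(X_adjusted, dtype=float)
    rng = np.random.default_rng(seed)
    if reference is None or pca is None:
        pca, _, reference = fit_archetypes(X, k, penalty=penalty, max_iter=max_iter,
                                           seed=int(rng.integers(2**31)))
    n = X.shape[0]
    clouds = []
    skipped = 0
    max_skipped = max(1, int(0.05 * n_boot))
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        scores_b = pca.transform(X[idx])
        try:
            sol_b = fit_simplex(scores_b, k, penalty=penalty, max_iter=max_iter,
                                seed=int(rng.integers(2**31)), delta=delta)
        except (SimplexFitError, ValueError):
            skipped += 1
            if skipped > max_skipped:
                raise SimplexFitError(
                    f"more than {max_skipped} bootstrap re-fits degenerate"
                )
            continue
        clouds.append(_align_vertices(reference.vertices_pc, sol_b.vertices_pc))
    clouds = np.asarray(clouds)
    means = clouds.mean(axis=0)
    covs = np.stack([np.cov(clouds[:, j, :].T) for j in range(k)])
    covs = covs.reshape(k, k - 1, k - 1)
    return BootstrapResult(n_boot=n_boot, clouds=clouds, covariances=covs,
                           means=means, n_skipped=skipped)


def reconstruct_full_space(solution: ArchetypeSolution, pca_model: PCAModel) -> np.ndarray:
    """Map PC-space vertices back to the original feature space."""
    if solution.vertices_pc.shape[1] != pca_model.n_components:
        raise ValueError("solution and PCA model have inconsistent dimensions")
    return pca_model.inverse_transform(solution.vertices_pc)


def distances_to_archetypes(X: np.ndarray, vertices_full: np.ndarray) -> np.ndarray:
    """Euclidean distance of every subject to every archetype (n x k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(vertices_full, dtype=float))
    if X.shape[1] != V.shape[1]:
        raise ValueError("dimension mismatch between data and vertices")
    return cdist(X, V)
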