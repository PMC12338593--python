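"""Feature enrichment near archetypes.

For each archetype, subjects are sorted by their Euclidean distance to that
archetype and split into equal-size bins (ten by default).  A feature is
"maximally enriched" at an archetype if the closest bin has larger values
than the rest of the sample (Mann-Whitney U test for continuous features,
hypergeometric test for Boolean ones) and the closest bin also carries the
extreme bin statistic across all bins; "minimally enriched" is the mirror
image.  Effect sizes are rank-biserial correlations derived from U, and
false-discovery-rate control (Benjamini-Hochberg, default threshold 0.1) is
applied within each archetype x direction family.

A leave-one-out procedure guards against circularity when the composition
components themselves are used as features: each component (or labeled system
of components) is dropped in turn, the archetypes are re-fit, and a feature
is called robust only if it stays significant in every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .polytope_fit import distances_to_archetypes, fit_archetypes

__all__ = [
    "BinAssignment",
    "bin_by_distance",
    "test_continuous",
    "rank_biserial",
    "test_boolean",
    "fdr_bh",
    "enrich_all",
    "leave_one_out",
]


@dataclass
class BinAssignment:
    """Distance-ordered bin labels for one archetype.

    ``labels`` holds, per subject, the 1-based bin index (1 = closest to the
    archetype); ``sizes`` the bin sizes, which differ by at most one with any
    remainder given to the closest bins first.
    """

    archetype_index: int
    labels: np.ndarray
    sizes: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.sizes)

    def bin_mask(self, b: int) -> np.ndarray:
        return self.labels == b


def bin_by_distance(distances: np.ndarray, n_bins: int = 10,
                    archetype_index: int = 0) -> BinAssignment:
    """Split subjects into contiguous distance bins, closest first.

    Subjects are sorted by ascending distance (stable, so ties keep input
    order); bin sizes are as equal as possible with remainders allocated to
    the bins closest to the archetype.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} subjects for {n_bins} bins, got {n}")
    order = np.argsort(d, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = b
        start += size
    return BinAssignment(archetype_index=archetype_index, labels=labels, sizes=sizes)


def _mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U statistic of x vs y and tie-corrected normal z (no continuity corr.).

    z is signed positive when x is stochastically larger than y.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    U1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return float(U1), 0.0
    z = (U1 - n1 * n2 / 2.0) / np.sqrt(var)
    return float(U1), float(z)


def test_continuous(feature: np.ndarray, bins: BinAssignment):
    """Mann-Whitney test of the closest bin against all other subjects.

    Returns ``(U, z, p_max, p_min)`` where ``U`` counts pairs favorable to
    the closest bin, ``z`` is the tie-corrected normal approximation (signed
    positive when the closest bin is stochastically larger), ``p_max`` the
    one-sided p for "closest bin larger" and ``p_min`` for "smaller".
    """
    feature = np.asarray(feature, dtype=float)
    mask = bins.bin_mask(1)
    x, y = feature[mask], feature[~mask]
    if np.all(feature == feature[0]):
        return float(len(x) * len(y) / 2.0), 0.0, 1.0, 1.0
    U1, z = _mannwhitney_z(x, y)
    p_max = float(stats.norm.sf(z))
    p_min = float(stats.norm.cdf(z))
    return U1, z, p_max, p_min


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation from a Mann-Whitney U statistic.

    ``r = 1 - 2 U / (n1 n2)``: with ``U`` counting pairs *unfavorable* to the
    closest bin, ``r = +1`` means every closest-bin value exceeds every other
    value.  Equivalently r is the difference between the proportions of
    favorable and unfavorable pairs.
    """
    if not 0 <= U <= n1 * n2:
        raise ValueError(f"U={U} outside [0, {n1 * n2}]")
    return 1.0 - 2.0 * U / (n1 * n2)


def test_boolean(flags: np.ndarray, bins: BinAssignment):
    """Hypergeometric test of success concentration in the closest bin.

    Returns ``(overlap, p_max, p_min)``: the number of successes in the
    closest bin, the upper-tail p (over-representation) and the lower-tail p
    (under-representation).
    """
    flags = np.asarray(flags).astype(bool)
    N = len(flags)
    K = int(flags.sum())
    if K == 0 or K == N:
        mask = bins.bin_mask(1)
        return int(flags[mask].sum()), 1.0, 1.0
    mask = bins.bin_mask(1)
    n1 = int(mask.sum())
    x = int(flags[mask].sum())
    p_max = float(stats.hypergeom.sf(x - 1, N, K, n1))
    p_min = float(stats.hypergeom.cdf(x, N, K, n1))
    return x, p_max, p_min


def fdr_bh(p_values: np.ndarray, q_threshold: float = 0.1):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, significant_flags)`` with monotonicity enforced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, reject


def _bin_profile(values: np.ndarray, bins: BinAssignment, boolean: bool) -> np.ndarray:
    stat = np.mean if boolean else np.median
    return np.array([stat(values[bins.bin_mask(b)]) for b in range(1, bins.n_bins + 1)])


def enrich_all(
    features: pd.DataFrame,
    distances: np.ndarray,
    feature_kinds: dict | None = None,
    n_bins: int = 10,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Full enrichment table: every feature x archetype x direction.

    ``features`` is a subject x feature DataFrame (median-imputed, no
    missing values); ``distances`` the subject x archetype Euclidean distance
    matrix; ``feature_kinds`` maps feature name to ``'continuous'`` (default)
    or ``'boolean'``.  BH-FDR is applied separately within each archetype x
    direction family, and a result is flagged significant only if its q-value
    passes the threshold *and* the closest bin carries the extreme bin
    statistic in the tested direction (median for continuous features,
    success rate for Boolean ones).
    """
    distances = np.asarray(distances, dtype=float)
    if len(features) != distances.shape[0]:
        raise ValueError("features and distances have different numbers of subjects")
    if features.isna().any().any():
        raise ValueError("features contain missing values; impute first")
    feature_kinds = feature_kinds or {}
    n, k = distances.shape
    rows = []
    for a in range(k):
        bins = bin_by_distance(distances[:, a], n_bins=n_bins, archetype_index=a)
        n1 = int(bins.sizes[0])
        n2 = n - n1
        for name in features.columns:
            vals = features[name].to_numpy(dtype=float)
            kind = feature_kinds.get(name, "continuous")
            boolean = kind == "boolean"
            profile = _bin_profile(vals, bins, boolean)
            mask1 = bins.bin_mask(1)
            med_diff = (np.median(vals[mask1]) - np.median(vals[~mask1])
                        if not boolean else
                        float(vals[mask1].mean() - vals[~mask1].mean()))
            if boolean:
                overlap, p_max, p_min = test_boolean(vals, bins)
                U = z = np.nan
                r = float(vals[mask1].mean() - vals[~mask1].mean())
            else:
                U, z, p_max, p_min = test_continuous(vals, bins)
                r = rank_biserial(n1 * n2 - U, n1, n2)  # U unfavorable to bin 1
            for direction, p in (("max", p_max), ("min", p_min)):
                extreme = profile.argmax() if direction == "max" else profile.argmin()
                rows.append({
                    "feature": name, "archetype": a, "direction": direction,
                    "test": "hypergeometric" if boolean else "mann-whitney",
                    "U": U, "z": z, "p": p, "r": r, "n": n,
                    "median_diff": med_diff,
                    "bin_profile": profile.tolist(),
                    "closest_bin_extremum": bool(extreme == 0),
                })
    result = pd.DataFrame(rows)
    result["q"] = np.nan
    result["significant"] = False
    for (a, direction), idx in result.groupby(["archetype", "direction"]).groups.items():
        q, reject = fdr_bh(result.loc[idx, "p"].to_numpy(), q_threshold)
        result.loc[idx, "q"] = q
        result.loc[idx, "significant"] = reject & result.loc[idx, "closest_bin_extremum"]
    return result


def _match_archetypes(ref_distances: np.ndarray, new_distances: np.ndarray) -> np.ndarray:
    """Match archetype labels across fits by subject distance-profile similarity."""
    k = ref_distances.shape[1]
    corr = np.corrcoef(ref_distances.T, new_distances.T)[:k, k:]
    _, col = linear_sum_assignment(-corr)
    return col


def leave_one_out(
    X_adjusted: np.ndarray,
    features: pd.DataFrame,
    k: int,
    feature_kinds: dict | None = None,
    n_bins: int = 10,
    q_threshold: float = 0.1,
    penalty: float = 5.0,
    seed: int | None = None,
    component_ids: list | None = None,
    systems: dict | None = None,
    mode: str = "components",
):
    """Drop-one-component robustness of the enrichment analysis.

    In ``mode='components'`` each of the ``D`` columns is excluded in turn;
    in ``mode='systems'`` whole labeled groups of columns (``systems`` maps
    system name to a list of component ids) are excluded together.  For every
    iteration the archetypes are re-fit on the reduced matrix, archetype
    labels are matched back to the reference fit via subject distance
    profiles, and the enrichment analysis is repeated.  A feature x archetype
    x direction result is marked robust if it is significant in the reference
    analysis and in every feasible iteration.

    Returns ``(per_iteration, robustness)``: a dict of enrichment tables
    keyed by the dropped component/system, and a summary DataFrame.
    """
    X = np.asarray(X_adjusted, dtype=float)
    n, D = X.shape
    if D < k:
        raise ValueError(f"need D >= k={k} components for leave-one-out")
    component_ids = component_ids or [f"IC{j + 1:02d}" for j in range(D)]
    if mode == "components":
        groups = {cid: [j] for j, cid in enumerate(component_ids)}
    elif mode == "systems":
        if not systems:
            raise ValueError("mode='systems' requires a systems mapping")
        col_of = {cid: j for j, cid in enumerate(component_ids)}
        groups = {name: [col_of[c] for c in comps] for name, comps in systems.items()}
    else:
        raise ValueError("mode must be 'components' or 'systems'")

    rng = np.random.default_rng(seed)
    _, _, ref_sol = fit_archetypes(X, k, penalty=penalty, seed=int(rng.integers(2**31)))
    ref_dist = distances_to_archetypes(X, ref_sol.vertices_full)
    ref_table = enrich_all(features, ref_dist, feature_kinds, n_bins, q_threshold)

    per_iteration: dict[str, pd.DataFrame] = {}
    failed: list[str] = []
    for name, cols in groups.items():
        keep = [j for j in range(D) if j not in cols]
        if len(keep) < k - 1:
            failed.append(name)
            continue
        try:
            _, _, sol = fit_archetypes(X[:, keep], k, penalty=penalty,
                                       seed=int(rng.integers(2**31)))
        except Exception:
            failed.append(name)
            continue
        dist = distances_to_archetypes(X[:, keep], sol.vertices_full)
        match = _match_archetypes(ref_dist, dist)
        table = enrich_all(features, dist[:, match], feature_kinds, n_bins, q_threshold)
        per_iteration[name] = table

    key = ["feature", "archetype", "direction"]
    summary = ref_table[key + ["significant"]].rename(
        columns={"significant": "reference_significant"})
    always = np.ones(len(summary), dtype=bool)
    for name, table in per_iteration.items():
        merged = summary[key].merge(table[key + ["significant"]], on=key, how="left")
        always &= merged["significant"].fillna(False).to_numpy(dtype=bool)
    summary["robust"] = summary["reference_significant"].to_numpy(dtype=bool) & always
    summary.attrs["n_iterations"] = len(per_iteration)
    summary.attrs["failed_iterations"] = failed
    return per_iteration, summary


def average_systems(features: pd.DataFrame, systems: dict) -> pd.DataFrame:
    """Average feature columns within labeled systems into composite features."""
    out = {}
    for name, members in systems.items():
        missing = [m for m in members if m not in features.columns]
        if missing:
            raise ValueError(f"system {name!r} references unknown features {missing}")
        out[name] = features[members].mean(axis=1)
    return pd.DataFrame(out, index=features.index)
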