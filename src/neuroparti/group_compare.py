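"""Group comparisons of archetype distances.

Held-out samples (e.g. clinical groups) are projected onto the reference PC
basis in which the archetypes were defined, and each subject's Euclidean
distances to the archetypes are computed in the original feature space.  Per
archetype, a Kruskal-Wallis test (with the standard tie correction) compares
the distance distributions across groups; when it is significant, all
pairwise Mann-Whitney post-hoc tests are run with Benjamini-Hochberg FDR at
0.05 within the archetype's pairwise family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compositions import AdjustedTable
from .enrichment import _mannwhitney_z, fdr_bh
from .polytope_fit import PCAModel

__all__ = ["GroupDistanceReport", "project_samples", "compare_groups"]


@dataclass
class GroupDistanceReport:
    """Kruskal-Wallis results per archetype plus post-hoc pairwise tests."""

    kruskal: pd.DataFrame   # archetype, H, df, p
    posthoc: pd.DataFrame   # archetype, group_a, group_b, z, median_diff, p, q, significant
    alpha: float
    q_threshold: float


def project_samples(
    X_new: np.ndarray | AdjustedTable,
    pca_model: PCAModel,
    component_ids: list | None = None,
    reference_component_ids: list | None = None,
) -> np.ndarray:
    """Project held-out (already adjusted) samples onto the reference PC basis.

    Centering uses the *reference* mean, so a sample equal to the reference
    mean maps to the origin of the archetype space.  If component ids are
    supplied for both sides they must match exactly (order included).
    """
    if isinstance(X_new, AdjustedTable):
        component_ids = list(X_new.component_ids)
        X_new = X_new.values
    X_new = np.asarray(X_new, dtype=float)
    if component_ids is not None and reference_component_ids is not None:
        if list(component_ids) != list(reference_component_ids):
            missing = [c for c in reference_component_ids if c not in component_ids]
            extra = [c for c in component_ids if c not in reference_component_ids]
            raise ValueError(
                f"component mismatch: missing {missing}, unexpected {extra}"
            )
    if X_new.shape[1] != pca_model.mean.shape[0]:
        raise ValueError(
            f"expected {pca_model.mean.shape[0]} components, got {X_new.shape[1]}"
        )
    return pca_model.transform(X_new)


def compare_groups(
    distances: np.ndarray,
    group_labels,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
    always_posthoc: bool = False,
) -> GroupDistanceReport:
    """Kruskal-Wallis + pairwise Mann-Whitney tests of archetype distances.

    ``distances`` is the pooled ``(n, k)`` distance matrix over all subjects
    and ``group_labels`` a length-``n`` vector of group names.  Post-hoc
    pairwise tests (reported with tie-corrected z, median difference and
    BH-adjusted q within each archetype family) are run when the
    Kruskal-Wallis test is significant at ``alpha`` (or always, if
    ``always_posthoc``).
    """
    distances = np.atleast_2d(np.asarray(distances, dtype=float))
    labels = np.asarray(group_labels)
    if len(labels) != distances.shape[0]:
        raise ValueError("group labels and distances disagree on subject count")
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    k = distances.shape[1]
    kw_rows, ph_rows = [], []
    for a in range(k):
        samples = [distances[labels == g, a] for g in groups]
        H, p = stats.kruskal(*samples)
        kw_rows.append({"archetype": a, "H": float(H),
                        "df": len(groups) - 1, "p": float(p)})
        if p < alpha or always_posthoc:
            for ga, gb in itertools.combinations(groups, 2):
                xa = distances[labels == ga, a]
                xb = distances[labels == gb, a]
                _, z = _mannwhitney_z(xa, xb)
                p2 = float(2 * stats.norm.sf(abs(z)))
                ph_rows.append({
                    "archetype": a, "group_a": ga, "group_b": gb,
                    "z": z, "median_diff": float(np.median(xa) - np.median(xb)),
                    "p": min(p2, 1.0),
                })
    posthoc = pd.DataFrame(ph_rows, columns=["archetype", "group_a", "group_b",
                                             "z", "median_diff", "p"])
    posthoc["q"] = np.nan
    posthoc["significant"] = False
    if len(posthoc):
        for a, idx in posthoc.groupby("archetype").groups.items():
            q, reject = fdr_bh(posthoc.loc[idx, "p"].to_numpy(), q_threshold)
            posthoc.loc[idx, "q"] = q
            posthoc.loc[idx, "significant"] = reject
    return GroupDistanceReport(
        kruskal=pd.DataFrame(kw_rows), posthoc=posthoc,
        alpha=alpha, q_threshold=q_threshold,
    )
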