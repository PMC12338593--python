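"""Adjusted proportion-of-variance tables.

Each subject's resting-state-network (RSN) variance profile is expressed as a
composition: the variance explained by each network divided by the total over
all retained networks, so every row is non-negative and sums to one.  Before
any geometric analysis the compositions are adjusted for nuisance covariates
(age, gender, in-scanner motion summaries) by per-column ordinary least
squares; the adjusted value is the residual plus the column mean, which keeps
the numbers on the proportion scale.  Behavioral feature tables may contain
missing entries, which are replaced by the per-feature median of the observed
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "ConfoundTable",
    "AdjustedTable",
    "normalize_variance",
    "adjust_confounds",
    "impute_median",
    "read_table",
    "write_table",
]


@dataclass
class CompositionTable:
    """Subject x component matrix of variance proportions.

    ``values`` is an ``(n, D)`` float array; rows are subjects, columns are
    components (e.g. ICA-derived networks).  Valid pre-adjustment tables are
    non-negative with unit row sums; use :meth:`validate` to check.
    """

    subject_ids: list
    component_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.component_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.component_ids)} components"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        """Check compositional invariants (non-negativity, unit row sums)."""
        if not np.all(np.isfinite(self.values)):
            raise ValueError("composition table contains non-finite values")
        if np.any(self.values < 0):
            bad = [self.subject_ids[i] for i in np.where((self.values < 0).any(axis=1))[0]]
            raise ValueError(f"negative proportions for subjects {bad[:5]}")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=atol):
            bad = [self.subject_ids[i] for i in np.where(np.abs(sums - 1.0) > atol)[0]]
            raise ValueError(f"row sums differ from 1 for subjects {bad[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.component_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class ConfoundTable:
    """Subject x confound matrix (age, gender dummy, mFD, mDVARS, % outliers)."""

    subject_ids: list
    confound_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.confound_ids)):
            raise ValueError("confound values shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("confound table contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.confound_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConfoundTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class AdjustedTable(CompositionTable):
    """Composition table after confound regression.

    ``coefficients`` holds the per-component OLS coefficients on
    ``[1, confounds]`` (shape ``(1 + C, D)``); ``column_means`` the original
    column means that were added back to the residuals.  Adjusted rows are no
    longer guaranteed to sum to one and may contain small negative values.
    """

    coefficients: np.ndarray = field(default=None)
    confound_ids: list = field(default_factory=list)
    column_means: np.ndarray = field(default=None)


def normalize_variance(
    raw: np.ndarray | pd.DataFrame,
    subject_ids=None,
    component_ids=None,
) -> CompositionTable:
    """Convert raw per-component variances into per-subject proportions.

    Each row is divided by its own sum, so the result expresses the variance
    explained by each component as a proportion of the total across all
    components for that subject.
    """
    if isinstance(raw, pd.DataFrame):
        subject_ids = list(raw.index)
        component_ids = list(raw.columns)
        raw = raw.to_numpy(dtype=float)
    raw = np.asarray(raw, dtype=float)
    n, d = raw.shape
    if subject_ids is None:
        subject_ids = [f"s{i:04d}" for i in range(n)]
    if component_ids is None:
        component_ids = [f"IC{j + 1:02d}" for j in range(d)]
    if np.any(raw < 0):
        bad = [subject_ids[i] for i in np.where((raw < 0).any(axis=1))[0]]
        raise ValueError(f"negative variance entries for subjects {bad[:5]}")
    sums = raw.sum(axis=1)
    if np.any(sums <= 0):
        bad = [subject_ids[i] for i in np.where(sums <= 0)[0]]
        raise ValueError(f"zero total variance for subjects {bad[:5]}")
    values = np.array([_normalize_row(row) for row in raw])
    return CompositionTable(subject_ids, component_ids, values)


def _normalize_row(x: np.ndarray) -> np.ndarray:
    # A row whose sum is already 1 up to summation rounding is left exactly
    # unchanged: dividing it again would dither the values by an ulp per
    # pass, so this tolerance is what makes normalization exactly idempotent.
    s = x.sum()
    if abs(s - 1.0) <= 16 * np.finfo(float).eps * len(x):
        return x
    return x / s


def adjust_confounds(comp: CompositionTable, conf: ConfoundTable,
                     renormalize: bool = False) -> AdjustedTable:
    """Regress confounds out of every component column.

    Fits ordinary least squares of each composition column on an intercept
    plus all confounds, and returns residual + column mean so that adjusted
    values stay on the proportion scale (column means are preserved).  Rows
    no longer sum to exactly one afterwards; ``renormalize=True`` clips at
    zero and re-divides each row by its sum for users who want to stay on
    the simplex.  Raises if subjects are misaligned or the design matrix is
    rank deficient.
    """
    if list(comp.subject_ids) != list(conf.subject_ids):
        raise ValueError("subject ids of composition and confound tables do not match")
    X = np.column_stack([np.ones(conf.values.shape[0]), conf.values])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        collinear = []
        for j, name in enumerate(conf.confound_ids):
            sub = X[:, : j + 2]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                collinear.append(name)
        raise ValueError(f"confound design is rank deficient; collinear: {collinear}")
    beta, *_ = np.linalg.lstsq(X, comp.values, rcond=None)
    resid = comp.values - X @ beta
    col_means = comp.values.mean(axis=0)
    adjusted = resid + col_means
    if renormalize:
        adjusted = np.clip(adjusted, 0.0, None)
        adjusted = adjusted / adjusted.sum(axis=1)[:, None]
    return AdjustedTable(
        subject_ids=list(comp.subject_ids),
        component_ids=list(comp.component_ids),
        values=adjusted,
        coefficients=beta,
        confound_ids=list(conf.confound_ids),
        column_means=col_means,
    )


def impute_median(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Replace missing feature entries by the per-feature median.

    Returns the completed table and a report of the percentage of missing
    values per feature.  A feature with no observed values at all is an error.
    """
    features = features.copy()
    n = len(features)
    if n == 0:
        raise ValueError("empty feature table")
    missing_pct = features.isna().mean(axis=0) * 100.0
    fully_missing = missing_pct[missing_pct >= 100.0].index.tolist()
    if fully_missing:
        raise ValueError(f"features with no observed values: {fully_missing}")
    medians = features.median(axis=0, skipna=True)
    completed = features.fillna(medians)
    missing_pct.name = "pct_missing"
    return completed, missing_pct


def read_table(path, kind: str = "generic") -> pd.DataFrame:
    """Read a TSV/CSV table with a header row and subject ids in column 0.

    Missing values may be encoded as empty cells or ``NA``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index_label="subject_id", na_rep="NA")
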