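"""Cross-profile statistics: Spearman correlations, confusion linkage, PCA.

Similarity of AU tuning between two trained groups is measured with
Spearman's rank correlation over the flattened 20 x 11 profiles, with the
null-image cells excluded (they are identically zero after baseline
subtraction), leaving n = 200 paired values.  All 49 unit pairings give a
7 x 7 correlation matrix, which is itself rank-correlated with the
database-swapped confusion matrix over its 49 cells.  For a compact
summary, each profile is reduced to 20 signed extrema (one peak or trough
per AU), the 14 reduced profiles (7 expressions x 2 databases) form a
20 x 14 feature matrix, and a mean-centered PCA maps every
(expression, database) pair into component space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .au import AU_IDS, EXPRESSIONS, N_AUS, N_EXPRESSIONS
from .probe import ProfileSet

BONFERRONI_ALPHA = 0.05


@dataclass
class CorrelationMatrix:
    """7x7 Spearman correlations between two groups' unit profiles."""

    rs: np.ndarray              # (7, 7)
    p: np.ndarray               # (7, 7)
    n_pairs: int
    row_group: str              # group whose units index the rows
    col_group: str

    def transpose(self) -> "CorrelationMatrix":
        return CorrelationMatrix(self.rs.T.copy(), self.p.T.copy(), self.n_pairs,
                                 self.col_group, self.row_group)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rs, index=list(EXPRESSIONS), columns=list(EXPRESSIONS))


@dataclass(frozen=True)
class ReducedProfile:
    """Per-AU signed extremum (peak or trough) of one unit's profile."""

    values: np.ndarray          # (20,)
    unit: str
    database: str


@dataclass
class PCAResult:
    loadings: np.ndarray        # (n_components, 20) per-AU loadings
    scores: np.ndarray          # (14, n_components)
    explained_variance_ratio: np.ndarray
    columns: list[tuple[str, str]]  # (database, expression) per observation


def spearman_rs(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided large-sample p value.

    Ranks use midranks for ties; rs is the Pearson correlation of the
    ranks.  Raises if either input has zero rank variance.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def profile_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray, exclude_null: bool = True
) -> tuple[float, float]:
    """Spearman rs between two (20, 11) unit profiles.

    With ``exclude_null`` (default) the intensity-0 column is dropped,
    leaving 20 x 10 = 200 paired values.
    """
    if profile_a.shape != profile_b.shape:
        raise ValueError("profiles must have identical shape")
    a, b = (p[:, 1:] if exclude_null else p for p in (profile_a, profile_b))
    return spearman_rs(a.ravel(), b.ravel())


def per_expression_correlations(
    profiles_a: ProfileSet, profiles_b: ProfileSet, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Same-expression profile correlations with Bonferroni significance flags."""
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    alpha = BONFERRONI_ALPHA / N_EXPRESSIONS
    rows = []
    for e, label in enumerate(EXPRESSIONS):
        rs, p = profile_correlation(profiles_a.responses[e], profiles_b.responses[e])
        rows.append({"expression": label, "rs": rs, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def cross_correlation_matrix(
    profiles_a: ProfileSet, profiles_b: ProfileSet,
    orientation: str = "a-rows", names: tuple[str, str] = ("A", "B"),
) -> CorrelationMatrix:
    """All 49 cross-group profile correlations.

    ``orientation="a-rows"`` puts group A's units on the rows; swapping the
    orientation transposes the matrix without changing any value.
    """
    rs = np.zeros((N_EXPRESSIONS, N_EXPRESSIONS))
    p = np.zeros_like(rs)
    for i in range(N_EXPRESSIONS):
        for j in range(N_EXPRESSIONS):
            rs[i, j], p[i, j] = profile_correlation(
                profiles_a.responses[i], profiles_b.responses[j]
            )
    m = CorrelationMatrix(rs, p, n_pairs=20 * 10, row_group=names[0], col_group=names[1])
    if orientation == "a-rows":
        return m
    if orientation == "b-rows":
        return m.transpose()
    raise ValueError("orientation must be 'a-rows' or 'b-rows'")


def correlate_with_confusion(corr: CorrelationMatrix, confusion: np.ndarray,
                             confusion_true_group: str | None = None) -> tuple[float, float]:
    """Spearman rs between the 49 profile correlations and 49 choice rates.

    The correlation matrix's row axis must correspond to the confusion
    matrix's true-label axis (the group whose database supplied the test
    images); pass ``confusion_true_group`` to have the convention checked.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.shape != (N_EXPRESSIONS, N_EXPRESSIONS):
        raise ValueError("confusion matrix must be 7x7")
    if confusion_true_group is not None and confusion_true_group != corr.row_group:
        raise ValueError(
            f"axis mismatch: correlation rows are {corr.row_group!r} but confusion "
            f"true labels come from {confusion_true_group!r}; transpose the matrix"
        )
    return spearman_rs(corr.rs.ravel(), confusion.ravel())


def reduce_profile(profile: np.ndarray, unit: str = "", database: str = "") -> ReducedProfile:
    """Per AU, the maximum-magnitude response across intensities, sign kept.

    Magnitude ties resolve toward the higher intensity.
    """
    if profile.shape != (N_AUS, 11):
        raise ValueError(f"expected a (20, 11) profile, got {profile.shape}")
    mag = np.abs(profile)
    # argmax over the reversed intensity axis picks the highest-intensity tie
    idx = 10 - np.argmax(mag[:, ::-1], axis=1)
    return ReducedProfile(profile[np.arange(N_AUS), idx], unit, database)


def build_feature_matrix(reduced: list[ReducedProfile]) -> pd.DataFrame:
    """20 x 14 matrix of signed extrema; columns database-major in label order."""
    by_key = {(r.database, r.unit): r for r in reduced}
    if len(by_key) != 14:
        raise ValueError(f"need 14 distinct (database, unit) reduced profiles, got {len(by_key)}")
    databases = sorted({r.database for r in reduced})
    columns, data = [], []
    for db in databases:
        for label in EXPRESSIONS:
            if (db, label) not in by_key:
                raise ValueError(f"missing reduced profile for ({db!r}, {label!r})")
            columns.append((db, label))
            data.append(by_key[(db, label)].values)
    return pd.DataFrame(
        np.column_stack(data),
        index=[f"AU#{a}" for a in AU_IDS],
        columns=pd.MultiIndex.from_tuples(columns, names=["database", "expression"]),
    )


def run_pca(feature_matrix: pd.DataFrame, n_components: int = 3) -> PCAResult:
    """Mean-centered (not variance-scaled) PCA of the 14 observations.

    Observations are the (database, expression) columns; variables are the
    20 AUs.  Components are ordered by explained variance.
    """
    from sklearn.decomposition import PCA

    X = feature_matrix.to_numpy().T  # (14, 20): observations x variables
    n_obs = X.shape[0]
    if n_components > n_obs - 1:
        raise ValueError(f"n_components must be <= {n_obs - 1} for {n_obs} observations")
    full = PCA(n_components=None)
    full.fit(X)
    ratios = full.explained_variance_ratio_
    return PCAResult(
        loadings=full.components_[:n_components],
        scores=full.transform(X)[:, :n_components],
        explained_variance_ratio=ratios,
        columns=list(feature_matrix.columns),
    )
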