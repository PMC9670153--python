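"""Test-set evaluation: confusion matrices and matched-vs-swapped statistics.

A confusion matrix holds per-expression choice rates (row = true label,
column = chosen label), computed per run on the single centered
un-augmented variant of each test image and averaged across runs.  In the
database-matched condition the test identities are the run's own held-out
split; in the database-swapped condition the test set comes from the
other database.  Group comparisons use a Welch two-sided t test on
per-run mean correct rates and a two-way ANOVA (group x expression,
type-II sums of squares) on per-run per-expression rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .au import EXPRESSIONS, N_EXPRESSIONS
from .network import ExpressionNet
from .training import PreparedDatabase, RunRecord


@dataclass
class ConfusionMatrix:
    """Run-averaged 7x7 choice-rate matrix with per-run detail retained."""

    matrix: np.ndarray          # (7, 7), rows sum to 1
    per_run: np.ndarray         # (n_runs, 7, 7)
    condition: str              # "matched" or "swapped"
    train_database: str
    test_database: str

    @property
    def n_runs(self) -> int:
        return self.per_run.shape[0]

    @property
    def correct_rates(self) -> np.ndarray:
        """Per-expression correct rates (the diagonal)."""
        return np.diag(self.matrix)

    @property
    def per_run_correct(self) -> np.ndarray:
        """(n_runs, 7) per-run per-expression correct rates."""
        return np.stack([np.diag(m) for m in self.per_run])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(EXPRESSIONS), columns=list(EXPRESSIONS))


@dataclass
class ConditionComparison:
    """Statistics comparing per-run correct rates of two evaluation groups."""

    group_names: tuple[str, str]
    means: np.ndarray           # (2, 7) per-expression mean correct rates
    sds: np.ndarray             # (2, 7)
    t_statistic: float | None = None
    t_p: float | None = None
    anova: pd.DataFrame | None = None


def _pairs_to_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    m = np.zeros((N_EXPRESSIONS, N_EXPRESSIONS))
    for i in range(N_EXPRESSIONS):
        sel = y_true == i
        if not sel.any():
            raise ValueError(f"empty test set for label {EXPRESSIONS[i]!r}")
        for j in range(N_EXPRESSIONS):
            m[i, j] = np.mean(y_pred[sel] == j)
    return m


def confusion_from_pairs(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    condition: str = "matched",
    train_database: str = "",
    test_database: str = "",
) -> ConfusionMatrix:
    """Build a run-averaged confusion matrix from per-run (true, predicted) pairs."""
    per_run = np.stack([_pairs_to_matrix(t, p) for t, p in pairs])
    return ConfusionMatrix(per_run.mean(axis=0), per_run, condition,
                           train_database, test_database)


def _predict_record(net: ExpressionNet, record: RunRecord, prepared: PreparedDatabase,
                    test_ids) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isin(prepared.eval_identity, list(test_ids))
    if not mask.any():
        raise ValueError("no evaluation images for the requested test identities")
    net.set_fc_params(record.fc_params)
    scores, _ = net.head_forward(record.standardize(prepared.eval_feats[mask]))
    return prepared.eval_labels[mask], np.argmax(scores, axis=1)


def confusion_matrix(
    records: list[RunRecord],
    prepared: PreparedDatabase,
    net: ExpressionNet,
) -> ConfusionMatrix:
    """Database-matched evaluation: each run tested on its own held-out identities."""
    pairs = []
    for rec in records:
        overlap = set(rec.split.test_ids) & (set(rec.split.train_ids) | set(rec.split.val_ids))
        if overlap:
            raise ValueError(f"test identities overlap train/validation: {sorted(overlap)}")
        pairs.append(_predict_record(net, rec, prepared, rec.split.test_ids))
    return confusion_from_pairs(pairs, "matched", prepared.name, prepared.name)


def swap_test_database(
    records: list[RunRecord],
    prepared_other: PreparedDatabase,
    net: ExpressionNet,
    test_ids_per_run: list[tuple[str, ...]] | None = None,
    train_database: str = "",
) -> ConfusionMatrix:
    """Database-swapped evaluation: runs tested on the other database's test sets.

    `test_ids_per_run` gives, for each run, which of the other database's
    identities form the test set (typically the other group's own per-run
    test split); by default every identity of the other database is used.
    """
    pairs = []
    for r, rec in enumerate(records):
        ids = (test_ids_per_run[r] if test_ids_per_run is not None
               else prepared_other.identities)
        pairs.append(_predict_record(net, rec, prepared_other, ids))
    condition = "matched" if prepared_other.name == train_database else "swapped"
    return confusion_from_pairs(pairs, condition, train_database, prepared_other.name)


def compare_correct_rates(
    a: ConfusionMatrix, b: ConfusionMatrix, test: str = "t",
    names: tuple[str, str] | None = None,
) -> ConditionComparison:
    """Welch t test and/or two-way ANOVA on per-run correct rates of two groups."""
    if a.n_runs < 2 or b.n_runs < 2:
        raise ValueError("need at least 2 runs per group")
    ra, rb = a.per_run_correct, b.per_run_correct
    names = names or (f"{a.train_database}-{a.condition}", f"{b.train_database}-{b.condition}")
    comp = ConditionComparison(
        group_names=names,
        means=np.stack([ra.mean(0), rb.mean(0)]),
        sds=np.stack([ra.std(0, ddof=1), rb.std(0, ddof=1)]),
    )
    if test == "t":
        with warnings.catch_warnings():
            # near-identical groups (e.g. ceiling accuracy in both) trip
            # scipy's catastrophic-cancellation warning; the t of ~0 is fine
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(ra.mean(1), rb.mean(1), equal_var=False)
        if np.isnan(t):  # identical zero-variance groups
            t, p = 0.0, 1.0
        comp.t_statistic, comp.t_p = float(t), float(p)
    elif test == "anova":
        comp.anova = two_way_anova(ra, rb, names)
    else:
        raise ValueError("test must be 't' or 'anova'")
    return comp


def two_way_anova(rates_a: np.ndarray, rates_b: np.ndarray,
                  names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Type-II two-way ANOVA (group x expression) on per-run correct rates."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for name, rates in zip(names, (rates_a, rates_b)):
        for run in range(rates.shape[0]):
            for e, label in enumerate(EXPRESSIONS):
                rows.append({"group": name, "expression": label, "rate": rates[run, e]})
    df = pd.DataFrame(rows)
    model = smf.ols("rate ~ C(group) * C(expression)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
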