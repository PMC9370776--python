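"""Best k-term linear predictors, cross-validated R2, and patient classification.

From the final candidate list, all C(p, k) subsets for k = 1..5 are fitted
exhaustively and the best per size is chosen by AICc.  Predictive power is
summarized by a cross-validated R2 computed from out-of-fold predictions
averaged over repeated random fold assignments, and per-patient predictions
are classified against a significant-weight-loss threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mc_search import SingularDesignError, fit_ols
from .screening import _as_matrix

__all__ = [
    "ModelReport",
    "ClassificationTable",
    "best_k_term_models",
    "cv_r2",
    "classify_predictions",
    "relative_se",
    "LABELS",
]

LABELS = ("correct(+)", "correct(-)", "overpredicted", "underpredicted")


@dataclass
class ModelReport:
    """A fitted k-term linear model and its selection/validation statistics."""

    response: str
    terms: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    se: np.ndarray  # [intercept, slopes...]
    rss: float
    aicc: float
    r2: float
    adj_r2: float
    fitted: np.ndarray
    cv_r2: dict[int, float] = field(default_factory=dict)
    n_candidates: int = 0  # number of subsets evaluated for this size

    def relative_se_percent(self) -> np.ndarray:
        return relative_se(self.coef, self.se[1:])

    def to_row(self) -> dict:
        row = {
            "response": self.response,
            "n_terms": len(self.terms),
            "terms": "+".join(self.terms),
            "aicc": self.aicc,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "intercept": self.intercept,
            "n_candidates": self.n_candidates,
        }
        for t, c, s in zip(self.terms, self.coef, self.se[1:]):
            row[f"coef[{t}]"] = c
            row[f"se[{t}]"] = s
        for k, v in self.cv_r2.items():
            row[f"cv_r2_{k}fold"] = v
        return row


def best_k_term_models(
    X,
    y,
    k_range=range(1, 6),
    response: str = "rwl",
) -> dict[int, ModelReport]:
    """Exhaustive best model per term count, selected by AICc.

    Ties are broken by smaller RSS, then lexicographic term names.  Singular
    subsets are skipped with a warning.
    """
    values, taxon_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = values.shape
    ks = sorted(set(int(k) for k in k_range))
    if ks and ks[-1] > p:
        raise ValueError(f"k up to {ks[-1]} requested but only {p} terms available")
    out: dict[int, ModelReport] = {}
    prev_rss = np.inf
    for k in ks:
        if n <= k + 3:
            raise ValueError(f"n={n} too small for {k}-term models (AICc undefined)")
        best: tuple[float, float, tuple[str, ...]] | None = None
        best_fit = None
        n_evaluated = 0
        for combo in itertools.combinations(range(p), k):
            names = tuple(taxon_ids[j] for j in combo)
            try:
                fit = fit_ols(values[:, combo], y)
            except SingularDesignError:
                warnings.warn(f"skipping singular subset {names}", stacklevel=2)
                continue
            n_evaluated += 1
            key = (fit.aicc, fit.rss, names)
            if best is None or key < best:
                best = key
                best_fit = fit
        if best_fit is None:
            raise ValueError(f"no non-singular {k}-term subset found")
        report = ModelReport(
            response=response,
            terms=best[2],
            coef=best_fit.coef,
            intercept=best_fit.intercept,
            se=best_fit.se,
            rss=best_fit.rss,
            aicc=best_fit.aicc,
            r2=best_fit.r2,
            adj_r2=best_fit.adj_r2,
            fitted=best_fit.fitted,
            n_candidates=n_evaluated,
        )
        # best-subset RSS can only improve as terms are added
        if report.rss > prev_rss + 1e-8:
            raise AssertionError("best-subset RSS increased with k; search is broken")
        prev_rss = report.rss
        out[k] = report
    return out


def _fold_assignment(
    n: int, n_folds: int, rng: np.random.Generator, strata: np.ndarray | None
) -> list[np.ndarray]:
    """Random fold assignment, optionally dealing each stratum round-robin."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    if strata is None:
        perm = rng.permutation(n)
        return [np.asarray(f) for f in np.array_split(perm, n_folds)]
    start = 0
    for s in np.unique(strata):
        members = rng.permutation(np.flatnonzero(strata == s))
        for i, idx in enumerate(members):
            folds[(start + i) % n_folds].append(idx)
        start += len(members)
    return [np.asarray(f, dtype=int) for f in folds]


def cv_r2(
    X,
    y,
    terms: list[str] | None = None,
    n_folds: int = 5,
    n_repeats: int = 200,
    seed: int = 0,
    strata: np.ndarray | None = None,
) -> float:
    """Cross-validated R2 from out-of-fold predictions averaged over repeats.

    Each repeat draws a fold assignment (optionally stratified, e.g. by the
    PS/NS group so no fold is outcome-empty), fits on the training folds and
    predicts the held-out patients; each patient's predictions are averaged
    over repeats and R2 = 1 - SS_res / SS_tot on those averages.  With
    ``n_folds == n`` this is leave-one-out: deterministic, a single repeat.
    """
    values, taxon_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n={n}")
    if terms is not None:
        col = {t: j for j, t in enumerate(taxon_ids)}
        values = values[:, [col[t] for t in terms]]
    loo = n_folds == n
    if loo:
        n_repeats = 1
    rng = np.random.default_rng(seed)
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    for _ in range(n_repeats):
        if loo:
            folds = [np.asarray([i]) for i in range(n)]
        else:
            folds = _fold_assignment(n, n_folds, rng, strata)
        for test_idx in folds:
            if len(test_idx) < 1:
                raise ValueError("empty cross-validation fold")
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            fit = fit_ols(values[mask], y[mask])
            preds = values[test_idx] @ fit.coef + fit.intercept
            pred_sum[test_idx] += preds
            pred_count[test_idx] += 1
    y_hat = pred_sum / pred_count
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class ClassificationTable:
    """Per-patient classification of predicted vs actual outcome."""

    frame: pd.DataFrame  # columns: patient, predicted, actual, label
    tallies: dict[str, int]

    @property
    def sum_correct(self) -> int:
        return self.tallies["correct(+)"] + self.tallies["correct(-)"]

    @property
    def sum_incorrect(self) -> int:
        return self.tallies["overpredicted"] + self.tallies["underpredicted"]

    @classmethod
    def from_labels(cls, labels) -> "ClassificationTable":
        """Build tallies from an existing label column alone."""
        labels = list(labels)
        bad = set(labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown classification labels: {sorted(bad)}")
        frame = pd.DataFrame(
            {
                "patient": range(1, len(labels) + 1),
                "predicted": np.nan,
                "actual": np.nan,
                "label": labels,
            }
        )
        tallies = {lab: labels.count(lab) for lab in LABELS}
        return cls(frame=frame, tallies=tallies)


def classify_predictions(
    predicted,
    actual,
    threshold: float = 10.0,
    patient_ids=None,
) -> ClassificationTable:
    """Classify each patient's prediction against the success threshold.

    The boundary convention is >=: a value exactly at the threshold counts as
    significant weight loss, both for the actual outcome and the prediction.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    pred_hit = predicted >= threshold
    act_hit = actual >= threshold
    labels = np.where(
        act_hit & pred_hit,
        "correct(+)",
        np.where(
            ~act_hit & ~pred_hit,
            "correct(-)",
            np.where(pred_hit & ~act_hit, "overpredicted", "underpredicted"),
        ),
    )
    if patient_ids is None:
        patient_ids = list(range(1, len(actual) + 1))
    frame = pd.DataFrame(
        {"patient": patient_ids, "predicted": predicted, "actual": actual, "label": labels}
    )
    tallies = {lab: int((labels == lab).sum()) for lab in LABELS}
    table = ClassificationTable(frame=frame, tallies=tallies)
    assert table.sum_correct + table.sum_incorrect == len(actual)
    return table


def relative_se(coef, se) -> np.ndarray:
    """Relative standard errors in percent, 100 * |se / coef|; NaN for zero coefs."""
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    out = np.full(coef.shape, np.nan)
    nz = coef != 0
    out[nz] = 100.0 * np.abs(se[nz] / coef[nz])
    if (~nz).any():
        warnings.warn("relative SE undefined for zero coefficients; reported as NaN")
    return out
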