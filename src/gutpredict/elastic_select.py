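"""Stability selection by repeated cross-validated elastic-net regression.

Each repeat draws a fresh fold assignment, cross-validates the penalty over a
fixed grid at a fixed mixing parameter, refits on all samples at the penalty
with the lowest mean CV squared error, and records which taxa carry nonzero
coefficients.  A taxon's occurrence is the percentage of repeats in which it
was selected; taxa clearing an occurrence threshold for either response are
the elastic-net candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path

from .screening import _as_matrix

__all__ = [
    "ENSettings",
    "run_selection",
    "run_selection_pair",
    "filter_candidates",
    "sweep_settings",
]


@dataclass(frozen=True)
class ENSettings:
    """Settings for one stability-selection cell.

    ``alpha`` is the L1/L2 mixing parameter (1 = lasso); ``n_folds`` one of
    {3, 5, 8, 15} in the canonical sweep.  The penalty grid has ``n_lambda``
    log-spaced values from the smallest all-zero penalty down by
    ``lambda_min_ratio``.
    """

    alpha: float = 1.0
    n_folds: int = 5
    n_repeats: int = 1000
    seed: int = 0
    n_lambda: int = 40
    lambda_min_ratio: float = 1e-2  # glmnet's default for p > n
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be positive")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, safe


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, settings: ENSettings) -> np.ndarray | None:
    n = len(y)
    yc = y - y.mean()
    lmax = np.max(np.abs(Xs.T @ yc)) / (n * settings.alpha)
    if lmax <= 0:
        return None
    return np.geomspace(lmax, lmax * settings.lambda_min_ratio, settings.n_lambda)


def run_selection(X, y, settings: ENSettings) -> pd.Series:
    """Occurrence percentage per taxon for a single response.

    Returns a Series indexed by taxon_id with values in [0, 100].
    Deterministic given ``settings.seed``.
    """
    values, taxon_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = values.shape
    if len(y) != n:
        raise ValueError(f"length mismatch: {n} samples vs {len(y)} response values")
    # canonical column order: occurrences depend on the labeled data only,
    # not on the order the columns arrive in (coordinate descent is not
    # exactly permutation-invariant for near-tied correlated columns)
    order = sorted(range(p), key=lambda j: taxon_ids[j])
    values = values[:, order]
    taxon_ids = [taxon_ids[j] for j in order]
    if settings.n_folds > n:
        raise ValueError(
            f"n_folds={settings.n_folds} exceeds n_samples={n}: folds would be empty"
        )
    if (values.std(axis=0) == 0).all():
        raise ValueError("all predictor columns are constant")

    rng = np.random.default_rng(settings.seed)
    Xs_full, _, _ = _standardize(values)
    grid = _lambda_grid(Xs_full, y, settings)
    counts = np.zeros(p)
    if grid is None:  # constant response: nothing is ever selected
        return pd.Series(counts, index=taxon_ids, name="occurrence")

    with warnings.catch_warnings():
        # small-n paths legitimately stop short of the duality-gap tolerance
        warnings.simplefilter("ignore", category=ConvergenceWarning)

        # the full-data coefficient path is fold-independent: compute it once
        _, coefs_full, _ = enet_path(
            Xs_full, y - y.mean(), l1_ratio=settings.alpha, alphas=grid, tol=settings.tol
        )
        nonzero_full = coefs_full != 0  # (p, n_lambda)

        n_lambda = len(grid)
        for _ in range(settings.n_repeats):
            perm = rng.permutation(n)
            folds = np.array_split(perm, settings.n_folds)
            sq_err = np.zeros(n_lambda)
            for test_idx in folds:
                mask = np.ones(n, dtype=bool)
                mask[test_idx] = False
                Xtr, ytr = values[mask], y[mask]
                Xtr_s, mean, sd = _standardize(Xtr)
                ybar = ytr.mean()
                _, coefs, _ = enet_path(
                    Xtr_s, ytr - ybar, l1_ratio=settings.alpha, alphas=grid, tol=settings.tol
                )
                Xte_s = (values[test_idx] - mean) / sd
                preds = Xte_s @ coefs + ybar  # (n_test, n_lambda)
                sq_err += ((preds - y[test_idx, None]) ** 2).sum(axis=0)
            best = int(np.argmin(sq_err))
            counts += nonzero_full[:, best]

    occurrence = 100.0 * counts / settings.n_repeats
    return pd.Series(occurrence, index=taxon_ids, name="occurrence")


def run_selection_pair(
    X, rwl: np.ndarray, dbmi: np.ndarray, settings: ENSettings
) -> pd.DataFrame:
    """Occurrence table for both responses (columns occurrence_rwl, occurrence_dbmi)."""
    child = np.random.SeedSequence(settings.seed).spawn(2)
    occ_rwl = run_selection(X, rwl, replace(settings, seed=int(child[0].generate_state(1)[0])))
    occ_dbmi = run_selection(X, dbmi, replace(settings, seed=int(child[1].generate_state(1)[0])))
    return pd.DataFrame(
        {"occurrence_rwl": occ_rwl, "occurrence_dbmi": occ_dbmi}
    ).rename_axis("taxon_id")


def filter_candidates(occurrences: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep taxa whose best occurrence over the two responses clears ``threshold`` (%).

    Sorted by that best occurrence, descending.
    """
    best = occurrences[["occurrence_rwl", "occurrence_dbmi"]].max(axis=1)
    kept = occurrences.loc[best >= threshold].copy()
    kept["max_occurrence"] = best[best >= threshold]
    return kept.sort_values("max_occurrence", ascending=False, kind="stable")


def sweep_settings(
    X,
    rwl: np.ndarray,
    dbmi: np.ndarray,
    alphas: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0),
    folds: tuple[int, ...] = (3, 5, 8, 15),
    n_repeats: int = 1000,
    seed: int = 0,
) -> dict[tuple[float, int], pd.DataFrame]:
    """Occurrence tables for every (alpha, n_folds) cell of the canonical sweep."""
    results: dict[tuple[float, int], pd.DataFrame] = {}
    children = np.random.SeedSequence(seed).spawn(len(alphas) * len(folds))
    i = 0
    for a in alphas:
        for k in folds:
            cell_seed = int(children[i].generate_state(1)[0])
            i += 1
            settings = ENSettings(alpha=a, n_folds=k, n_repeats=n_repeats, seed=cell_seed)
            results[(a, k)] = run_selection_pair(X, rwl, dbmi, settings)
    return results
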