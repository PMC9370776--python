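"""Per-taxon correlation screening and the banded correlation class.

Every predictor taxon is correlated with both responses (RWL and delta BMI)
and ranked by absolute correlation.  Taxa strongly correlated with *both*
responses receive a signed class in {0, +/-0.5, +/-1, +/-1.5, +/-2} that feeds
into the final evidence score: the strength is the smaller of the two absolute
correlations, expressed in percent and rounded to the nearest full percent,
and the sign is the common sign of the two correlations (opposite signs give
class 0).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_prep import PredictorMatrix

__all__ = ["correlate_all", "correlation_class", "screen"]

DEFAULT_BAND_EDGES = (45.0, 50.0, 55.0, 60.0)
DEFAULT_CLASS_VALUES = (0.5, 1.0, 1.5, 2.0)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, PredictorMatrix):
        return X.values, list(X.taxon_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def _columnwise_corr(values: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = stats.rankdata(values, axis=0)
        y = stats.rankdata(y)
    yc = y - y.mean()
    y_norm = np.sqrt((yc**2).sum())
    Xc = values - values.mean(axis=0)
    x_norm = np.sqrt((Xc**2).sum(axis=0))
    r = np.zeros(values.shape[1])
    ok = x_norm > 0
    r[ok] = (Xc[:, ok].T @ yc) / (x_norm[ok] * y_norm)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} constant taxon column(s); correlation set to 0",
            stacklevel=3,
        )
    return np.clip(r, -1.0, 1.0)


def correlate_all(X, y, method: str = "pearson") -> pd.DataFrame:
    """Correlate every taxon with ``y``; return a table ranked by |r| descending.

    Columns: ``taxon_id``, ``r``, ``abs_rank`` (1 = strongest).  Constant
    taxon columns get r = 0 with a warning; a constant ``y`` is an error.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    values, taxon_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValueError(
            f"length mismatch: {values.shape[0]} samples vs {y.shape[0]} response values"
        )
    if np.ptp(y) == 0:
        raise ValueError("response is constant; correlations are undefined")
    r = _columnwise_corr(values, y, method)
    out = pd.DataFrame({"taxon_id": taxon_ids, "r": r})
    out["abs_rank"] = stats.rankdata(-np.abs(r), method="average")
    return out.sort_values("abs_rank", kind="stable").reset_index(drop=True)


def _round_half_away(x: float) -> float:
    return float(np.floor(np.abs(x) + 0.5) * np.sign(x))


def correlation_class(
    r_rwl: float,
    r_dbmi: float,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    class_values: tuple[float, ...] = DEFAULT_CLASS_VALUES,
) -> float:
    """Signed strength class of a taxon correlated with both responses.

    The strength is min(|r_rwl|, |r_dbmi|) in percent, rounded half away from
    zero to a full percent, then mapped through half-open bands
    [45,50) -> 0.5, [50,55) -> 1, [55,60) -> 1.5, [60,100] -> 2 (configurable).
    The class carries the common sign of the two correlations; if their signs
    differ the class is 0.
    """
    for name, r in (("r_rwl", r_rwl), ("r_dbmi", r_dbmi)):
        if not -1.0 - 1e-9 <= r <= 1.0 + 1e-9:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    if len(class_values) != len(band_edges):
        raise ValueError("band_edges and class_values must have equal length")
    strength = _round_half_away(min(abs(r_rwl), abs(r_dbmi)) * 100.0)
    idx = int(np.searchsorted(band_edges, strength, side="right"))
    if idx == 0:
        return 0.0
    magnitude = class_values[idx - 1]
    s1, s2 = np.sign(r_rwl), np.sign(r_dbmi)
    if s1 == 0 or s2 == 0 or s1 != s2:
        return 0.0
    return float(s1 * magnitude)


def screen(
    X,
    rwl: np.ndarray,
    dbmi: np.ndarray,
    method: str = "pearson",
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    class_values: tuple[float, ...] = DEFAULT_CLASS_VALUES,
) -> pd.DataFrame:
    """Correlation records for all taxa against both responses.

    Returns columns ``taxon_id, r_rwl, r_dbmi, corr_class`` sorted by the
    minimum absolute correlation, strongest first.
    """
    c_rwl = correlate_all(X, rwl, method=method).set_index("taxon_id")["r"]
    c_dbmi = correlate_all(X, dbmi, method=method).set_index("taxon_id")["r"]
    _, taxon_ids = _as_matrix(X)
    rows = []
    for t in taxon_ids:
        rows.append(
            {
                "taxon_id": t,
                "r_rwl": c_rwl[t],
                "r_dbmi": c_dbmi[t],
                "corr_class": correlation_class(
                    c_rwl[t], c_dbmi[t], band_edges=band_edges, class_values=class_values
                ),
            }
        )
    out = pd.DataFrame(rows)
    strength = np.minimum(out["r_rwl"].abs(), out["r_dbmi"].abs())
    return (
        out.assign(_s=strength)
        .sort_values("_s", ascending=False, kind="stable")
        .drop(columns="_s")
        .reset_index(drop=True)
    )
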