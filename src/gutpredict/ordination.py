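"""Compositional ordination and group comparison: clr, PCA, PERMANOVA, tests.

The centered log-ratio (clr) transform maps per-sample proportions into
unconstrained space; Euclidean distances on clr data feed a permutation-based
multivariate ANOVA (implemented from the distance-matrix decomposition so the
permutation scheme and seed are fully controlled), and per-taxon group
differences are assessed by Mann-Whitney U tests with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClrMatrix",
    "PermanovaResult",
    "clr_transform",
    "permanova",
    "groupwise_tests",
    "zscore",
    "pca_scores",
]


@dataclass
class ClrMatrix:
    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray  # rows are centered log-ratios, each summing to 0

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 0.0, atol=1e-9):
            raise ValueError("clr rows must sum to 0 within 1e-9")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


def clr_transform(
    proportions,
    pseudocount: float | None = None,
    sample_ids=None,
    taxon_ids=None,
) -> ClrMatrix:
    """Centered log-ratio transform of a samples x taxa proportion matrix.

    ``pseudocount=None`` uses half the smallest nonzero value when zeros are
    present (and 0 otherwise); an explicit 0 with zeros present is an error.
    """
    if isinstance(proportions, pd.DataFrame):
        sample_ids = sample_ids or [str(i) for i in proportions.index]
        taxon_ids = taxon_ids or [str(c) for c in proportions.columns]
        proportions = proportions.to_numpy(dtype=float)
    X = np.asarray(proportions, dtype=float)
    if (X < 0).any():
        raise ValueError("proportions must be nonnegative")
    has_zero = (X == 0).any()
    if pseudocount is None:
        pseudocount = float(X[X > 0].min()) / 2.0 if has_zero else 0.0
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if has_zero and pseudocount == 0:
        raise ValueError("zeros present: a positive pseudocount is required")
    logs = np.log(X + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    n, p = clr.shape
    return ClrMatrix(
        sample_ids=list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)],
        taxon_ids=list(taxon_ids) if taxon_ids is not None else [f"x{j}" for j in range(p)],
        values=clr,
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    sst = d2.sum() / (2.0 * n)
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssa = sst - ssw
    return (ssa / (n_groups - 1)) / (ssw / (n - n_groups))


def permanova(
    distances: np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F comes from the between/within partition of squared
    distances; the p-value counts label permutations with F at least as large
    as observed, with the +1 correction, so p >= 1/(n_permutations + 1).
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    groups = np.asarray(groups)
    if len(groups) != D.shape[0]:
        raise ValueError("group labels must match the distance matrix size")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("at least two groups required")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 members: {small}")

    d2 = D**2
    f_obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), p_value=float(p), n_permutations=n_permutations, seed=seed
    )


def groupwise_tests(
    clr: ClrMatrix | pd.DataFrame,
    groups,
    fdr: float = 0.05,
    flag_q: float = 0.1,
) -> pd.DataFrame:
    """Per-taxon two-sided Mann-Whitney U tests between two groups with BH FDR.

    Returns columns taxon_id, u_stat, p_value, q_value, flagged (q < flag_q).
    All-tied taxa get p = 1 with a warning.
    """
    if isinstance(clr, ClrMatrix):
        values, taxon_ids = clr.values, clr.taxon_ids
    else:
        values, taxon_ids = clr.to_numpy(dtype=float), [str(c) for c in clr.columns]
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    u_stats = np.empty(values.shape[1])
    p_values = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        x, z = a[:, j], b[:, j]
        if np.ptp(np.concatenate([x, z])) == 0:
            warnings.warn(f"taxon {taxon_ids[j]!r} is all tied; p set to 1", stacklevel=2)
            u_stats[j] = len(x) * len(z) / 2.0
            p_values[j] = 1.0
            continue
        res = stats.mannwhitneyu(x, z, alternative="two-sided")
        u_stats[j] = res.statistic
        p_values[j] = res.pvalue
    q_values = stats.false_discovery_control(p_values, method="bh")
    return pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "u_stat": u_stats,
            "p_value": p_values,
            "q_value": q_values,
            "flagged": q_values < flag_q,
        }
    )


def zscore(values, axis: int = 0) -> np.ndarray:
    """Standardize each taxon across samples ((x - mean) / sd, sample sd, n-1).

    Constant taxa become all-zero columns with a warning.
    """
    X = np.asarray(values, dtype=float)
    mean = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, ddof=1, keepdims=True)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxon column(s); z-scores set to 0", stacklevel=2
        )
    safe = np.where(constant, 1.0, sd)
    out = (X - mean) / safe
    return np.where(np.broadcast_to(constant, X.shape), 0.0, out)


def pca_scores(values, tol: float = 1e-12) -> dict:
    """PCA of a column-centered matrix via SVD.

    Returns dict with ``scores`` (samples x components), ``loadings``
    (taxa x components) and ``variance_explained`` fractions over the kept
    (nonzero) components, which sum to 1.
    """
    X = np.asarray(values, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("PCA requires at least 2 taxa")
    centered = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > tol * max(1.0, s.max())
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s**2
    return {
        "scores": u * s,
        "loadings": vt.T,
        "variance_explained": var / var.sum(),
    }
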