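"""Monte-Carlo search over multiple linear regression models.

A pool of small linear models (term subsets of sizes 1..max_terms) is sampled
uniformly, each fitted by ordinary least squares and scored by the
small-sample Akaike criterion (AICc).  Per-taxon importance is a weighted
index of three pool statistics:

  A - frequency of the taxon among the best 5% of models by AICc,
  B - mean Akaike weight of the models containing the taxon,
  C - sign-consistency of the taxon's coefficient across containing models,
      multiplied by its selection frequency in the full pool.

Each component is min-max scaled to [0, 1] before weighting and the combined
index is normalized so the stage's best taxon scores exactly 1.  The search
iterates: at each stage of the reduction schedule the top-m taxa by index are
kept and the pool is re-sampled over the survivors, ending in a short final
term list.  Ranks from different weightings (and responses) are averaged into
the rank summary used by the final evidence score.

AICc uses the parameter count k = n_terms + 2 (intercept and error variance
are counted), so a 4-term model at n = 15 has k = 6:

    AICc = n * ln(RSS / n) + 2k + 2k(k + 1) / (n - k - 1)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .screening import _as_matrix

__all__ = [
    "MCSettings",
    "OLSFit",
    "ModelPool",
    "MCResult",
    "SingularDesignError",
    "WEIGHTING_1",
    "WEIGHTING_2",
    "GENUS_SCHEDULE",
    "GENUS_SCHEDULE_ALT",
    "SPECIES_SCHEDULE",
    "SPECIES_SCHEDULE_ALT",
    "fit_ols",
    "aicc_from_rss",
    "sample_models",
    "compute_index",
    "reduce_and_iterate",
    "average_ranks",
]

WEIGHTING_1 = (0.60, 0.20, 0.20)
WEIGHTING_2 = (0.45, 0.10, 0.45)

GENUS_SCHEDULE = (102, 44, 23, 15, 7)
GENUS_SCHEDULE_ALT = (102, 52, 25, 15, 7)
SPECIES_SCHEDULE = (106, 28, 16, 8)
SPECIES_SCHEDULE_ALT = (106, 32, 21, 15, 8)


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when a model's design matrix is rank deficient."""


@dataclass(frozen=True)
class MCSettings:
    """Settings of the Monte-Carlo model search.

    ``weights`` = (A, B, C) importance weights, nonnegative and summing to 1.
    ``reduction_schedule`` is a strictly decreasing list of list sizes whose
    first entry is the starting list size; ``None`` means a single stage over
    the full term list.
    """

    n_models: int = 100_000
    max_terms: int = 4
    weights: tuple[float, float, float] = WEIGHTING_1
    reduction_schedule: tuple[int, ...] | None = None
    seed: int = 0
    top_fraction: float = 0.05
    rss_floor: float = 1e-12
    max_draw_factor: int = 50

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1 within 1e-9")
        if self.reduction_schedule is not None:
            sched = tuple(self.reduction_schedule)
            if any(b >= a for a, b in zip(sched, sched[1:])):
                raise ValueError("reduction_schedule must be strictly decreasing")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class OLSFit:
    """An ordinary-least-squares fit with the AICc bookkeeping used here."""

    coef: np.ndarray  # slopes, one per term
    intercept: float
    se: np.ndarray  # standard errors: [intercept, slopes...]
    rss: float
    aicc: float
    n_params: int  # terms + intercept + error variance
    fitted: np.ndarray
    r2: float
    adj_r2: float


def aicc_from_rss(rss, n: int, n_terms) -> np.ndarray | float:
    """AICc with parameter count k = n_terms + 2 (intercept + error variance)."""
    k = np.asarray(n_terms) + 2
    denom = n - k - 1
    if np.any(denom <= 0):
        raise ValueError(f"AICc undefined: n={n} too small for {np.max(n_terms)} terms")
    return n * np.log(np.asarray(rss) / n) + 2 * k + 2 * k * (k + 1) / denom


def fit_ols(X_subset: np.ndarray, y: np.ndarray, rss_floor: float = 1e-12) -> OLSFit:
    """OLS with intercept on an n x k design of selected terms.

    A zero (or numerically tiny) residual sum of squares is floored at
    ``rss_floor`` with a warning so the AICc stays finite.  A rank-deficient
    design raises :class:`SingularDesignError`.
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    if X_subset.ndim == 2 and X_subset.shape[0] == 1 and len(y) > 1:
        X_subset = X_subset.T
    y = np.asarray(y, dtype=float)
    n, k = X_subset.shape
    if k + 2 + 1 > n:
        raise ValueError(f"too many parameters: {k} terms with n={n}")
    A = np.column_stack([np.ones(n), X_subset])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k + 1:
        raise SingularDesignError(
            f"singular design: rank {rank} < {k + 1}; collinear terms among columns"
        )
    fitted = A @ beta
    rss = float(((y - fitted) ** 2).sum())
    if rss < rss_floor:
        warnings.warn(
            f"residual sum of squares {rss:.3g} below floor; clamping to {rss_floor:.3g}",
            stacklevel=2,
        )
        rss = rss_floor
    aicc = float(aicc_from_rss(rss, n, k))
    df_resid = n - (k + 1)
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if ss_tot > 0 else np.nan
    return OLSFit(
        coef=beta[1:],
        intercept=float(beta[0]),
        se=se,
        rss=rss,
        aicc=aicc,
        n_params=k + 2,
        fitted=fitted,
        r2=r2,
        adj_r2=adj_r2,
    )


@dataclass
class ModelPool:
    """A pool of fitted term-subset models in flat array form.

    Model ``i`` covers ``flat_terms[offsets[i]:offsets[i+1]]`` (column indices
    into ``term_ids``) with matching slopes in ``flat_coefs``.
    """

    term_ids: list[str]
    sizes: np.ndarray  # (n_models,)
    offsets: np.ndarray  # (n_models + 1,)
    flat_terms: np.ndarray
    flat_coefs: np.ndarray
    aicc: np.ndarray  # (n_models,)

    @property
    def n_models(self) -> int:
        return len(self.sizes)

    def terms_of(self, i: int) -> tuple[int, ...]:
        return tuple(self.flat_terms[self.offsets[i] : self.offsets[i + 1]])

    def best_by_size(self) -> dict[int, tuple[tuple[str, ...], float]]:
        """Best model (term names, AICc) per subset size, ties by term order."""
        out: dict[int, tuple[tuple[str, ...], float]] = {}
        for i in np.argsort(self.aicc, kind="stable"):
            k = int(self.sizes[i])
            if k not in out:
                names = tuple(sorted(self.term_ids[j] for j in self.terms_of(i)))
                out[k] = (names, float(self.aicc[i]))
        return out


def _n_subsets(p: int, max_terms: int) -> int:
    return sum(math.comb(p, k) for k in range(1, max_terms + 1))


def _batch_fit(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, rss_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Fit all size-k subsets in ``idx`` (m, k) at once via normal equations."""
    m, k = idx.shape
    n = len(y)
    A = np.moveaxis(X[:, idx], 0, 1)  # (m, n, k)
    A = np.concatenate([np.ones((m, n, 1)), A], axis=2)
    At = A.transpose(0, 2, 1)
    G = At @ A
    b = At @ y
    try:
        beta = np.linalg.solve(G, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # a singular subset slipped in: fall back to minimum-norm solutions
        beta = np.stack([np.linalg.pinv(G[i]) @ b[i] for i in range(m)])
    yTy = float(y @ y)
    rss = np.maximum(yTy - np.einsum("mk,mk->m", b, beta), rss_floor)
    aicc = aicc_from_rss(rss, n, k)
    return aicc, beta[:, 1:]


def sample_models(terms: list[str], settings: MCSettings, X, y) -> ModelPool:
    """Sample a deduplicated pool of term subsets and fit them all.

    Subset sizes are uniform on {1..max_terms} and subsets uniform within a
    size; duplicates are redrawn until ``min(n_models, #subsets)`` unique
    models are collected or a draw cap is hit.  Deterministic given the seed.
    """
    if not terms:
        raise ValueError("term pool is empty")
    values, all_ids = _as_matrix(X)
    col_of = {t: j for j, t in enumerate(all_ids)}
    missing = [t for t in terms if t not in col_of]
    if missing:
        raise ValueError(f"terms not present in design matrix: {missing}")
    p = len(terms)
    max_terms = min(settings.max_terms, p)
    if p < settings.max_terms:
        raise ValueError(
            f"term pool of size {p} is smaller than max_terms={settings.max_terms}"
        )
    y = np.asarray(y, dtype=float)
    n = len(y)
    if max_terms + 3 > n:
        raise ValueError(f"max_terms={max_terms} too large for n={n} (AICc undefined)")

    target = min(settings.n_models, _n_subsets(p, max_terms))
    rng = np.random.default_rng(settings.seed)
    seen: set[tuple[int, ...]] = set()
    subsets: list[tuple[int, ...]] = []
    draws = 0
    cap = settings.max_draw_factor * max(settings.n_models, target)
    while len(subsets) < target and draws < cap:
        batch = max(256, target - len(subsets))
        sizes = rng.integers(1, max_terms + 1, size=batch)
        u = rng.random((batch, p))
        order = np.argsort(u, axis=1)
        for row, k in zip(order, sizes):
            sub = tuple(sorted(row[:k]))
            draws += 1
            if sub not in seen:
                seen.add(sub)
                subsets.append(sub)
                if len(subsets) >= target:
                    break

    Xcols = values[:, [col_of[t] for t in terms]]
    by_size: dict[int, list[int]] = {}
    for i, sub in enumerate(subsets):
        by_size.setdefault(len(sub), []).append(i)

    m = len(subsets)
    sizes_arr = np.fromiter((len(s) for s in subsets), dtype=int, count=m)
    offsets = np.concatenate([[0], np.cumsum(sizes_arr)])
    flat_terms = np.fromiter((j for s in subsets for j in s), dtype=int)
    flat_coefs = np.zeros(len(flat_terms))
    aicc = np.empty(m)
    for k, members in by_size.items():
        idx = np.asarray([subsets[i] for i in members], dtype=int)
        a, betas = _batch_fit(Xcols, y, idx, settings.rss_floor)
        aicc[members] = a
        for row, i in enumerate(members):
            flat_coefs[offsets[i] : offsets[i + 1]] = betas[row]
    return ModelPool(
        term_ids=list(terms),
        sizes=sizes_arr,
        offsets=offsets,
        flat_terms=flat_terms,
        flat_coefs=flat_coefs,
        aicc=aicc,
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-15:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def compute_index(pool: ModelPool, settings: MCSettings) -> pd.DataFrame:
    """Weighted importance index per taxon, normalized to a stage maximum of 1.

    Returns columns ``taxon_id, index, rank`` (rank 1 = most important,
    average ranks for ties), sorted by rank.
    """
    if pool.n_models == 0:
        raise ValueError("empty model pool")
    p = len(pool.term_ids)
    m = pool.n_models
    expand = np.repeat(np.arange(m), pool.sizes)  # model id per flat entry

    contain = np.zeros(p)
    np.add.at(contain, pool.flat_terms, 1.0)

    # A: frequency among the best top_fraction of models by AICc
    q = max(1, int(math.ceil(settings.top_fraction * m)))
    top_models = np.zeros(m, dtype=bool)
    top_models[np.argsort(pool.aicc, kind="stable")[:q]] = True
    a_count = np.zeros(p)
    np.add.at(a_count, pool.flat_terms[top_models[expand]], 1.0)
    comp_a = a_count / q

    # B: mean Akaike weight of containing models
    w = np.exp(-(pool.aicc - pool.aicc.min()) / 2.0)
    w /= w.sum()
    w_sum = np.zeros(p)
    np.add.at(w_sum, pool.flat_terms, w[expand])
    with np.errstate(invalid="ignore", divide="ignore"):
        comp_b = np.where(contain > 0, w_sum / np.maximum(contain, 1), 0.0)

    # C: coefficient sign consistency times selection frequency
    pos = np.zeros(p)
    neg = np.zeros(p)
    np.add.at(pos, pool.flat_terms[pool.flat_coefs > 0], 1.0)
    np.add.at(neg, pool.flat_terms[pool.flat_coefs < 0], 1.0)
    signed = pos + neg
    consistency = np.where(signed > 0, np.maximum(pos, neg) / np.maximum(signed, 1), 0.0)
    comp_c = consistency * (contain / m)

    wa, wb, wc = settings.weights
    raw = wa * _minmax(comp_a) + wb * _minmax(comp_b) + wc * _minmax(comp_c)
    top = raw.max()
    index = raw / top if top > 0 else np.ones_like(raw)
    rank = stats.rankdata(-index, method="average")
    out = pd.DataFrame({"taxon_id": pool.term_ids, "index": index, "rank": rank})
    return out.sort_values(["rank", "taxon_id"], kind="stable").reset_index(drop=True)


@dataclass
class MCResult:
    """All stage tables of one reduction run plus the surviving final list."""

    stage_tables: list[pd.DataFrame]
    stage_sizes: list[int]
    final_terms: list[str]
    settings: MCSettings

    @property
    def full_table(self) -> pd.DataFrame:
        return self.stage_tables[0]

    @property
    def final_table(self) -> pd.DataFrame:
        return self.stage_tables[-1]


def reduce_and_iterate(terms: list[str], X, y, settings: MCSettings) -> MCResult:
    """Run the staged reduction: sample, score, keep the top-m, repeat.

    The schedule's first entry must not exceed the starting list size; each
    later stage keeps that many taxa (ties broken by index then taxon ID) and
    re-samples the pool over the survivors.
    """
    schedule = settings.reduction_schedule or (len(terms),)
    if schedule[0] > len(terms):
        raise ValueError(
            f"schedule start {schedule[0]} exceeds term list size {len(terms)}"
        )
    stage_seeds = np.random.SeedSequence(settings.seed).spawn(len(schedule))
    current = list(terms)
    tables: list[pd.DataFrame] = []
    sizes: list[int] = []
    for stage, m in enumerate(schedule):
        if m > len(current):
            raise ValueError(f"schedule value {m} exceeds current list size {len(current)}")
        if m < len(current):
            prev = tables[-1]
            keep = prev.sort_values(["index", "taxon_id"], ascending=[False, True], kind="stable")
            current = keep["taxon_id"].head(m).tolist()
        stage_settings = replace(
            settings,
            seed=int(stage_seeds[stage].generate_state(1)[0]),
            reduction_schedule=None,
        )
        pool = sample_models(current, stage_settings, X, y)
        tables.append(compute_index(pool, stage_settings))
        sizes.append(len(current))
    return MCResult(
        stage_tables=tables,
        stage_sizes=sizes,
        final_terms=list(tables[-1]["taxon_id"]),
        settings=settings,
    )


def average_ranks(
    full_tables: list[pd.DataFrame], final_tables: list[pd.DataFrame]
) -> pd.DataFrame:
    """Average full-list and final-list ranks across weightings/responses.

    A taxon absent from every table of a kind gets NaN (a missing marker, not
    an imputed rank); a taxon present in only some tables is averaged over the
    tables that contain it.
    """
    if not full_tables:
        raise ValueError("at least one weighting's stage tables are required")

    def _avg(tables: list[pd.DataFrame]) -> pd.Series:
        ranks = [t.set_index("taxon_id")["rank"] for t in tables]
        return pd.concat(ranks, axis=1).mean(axis=1, skipna=True)

    avg_full = _avg(full_tables)
    avg_final = _avg(final_tables) if final_tables else pd.Series(dtype=float)
    out = pd.DataFrame({"avg_rank_full": avg_full, "avg_rank_final": avg_final})
    return out.rename_axis("taxon_id")
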