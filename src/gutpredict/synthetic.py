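"""Synthetic cohort generator.

Produces abundance tables and outcomes with the statistical structure the
downstream analysis assumes: a heavy-tailed (power-law mean, log-normal)
compositional community, a bimodal relative-weight-loss outcome, and a
configurable number of "planted" taxa whose abundance is rotated toward the
outcome to hit a target correlation on the closed (proportion) scale.

The log-normal map attenuates correlations injected in log space, and closure
attenuates them further, so the generator calibrates the latent correlation
empirically on a large auxiliary sample before drawing the actual cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_prep import (
    SUCCESS_THRESHOLD,
    AbundanceTable,
    CohortOutcomes,
    load_abundance,
    load_outcomes,
)

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "CalibrationError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


class CalibrationError(ValueError):
    """Target planted correlation is unattainable for the chosen noise level."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``dominance`` is the power-law exponent of the mean log-abundance decay
    (mean abundance of the rank-j taxon decays as (j + dominance_offset) to
    the power -dominance); the defaults make the top ~10% of taxa carry
    ~98-99% of the community mass without a single taxon dominating the
    whole community.
    """

    n_patients: int = 15
    n_taxa_raw: int = 1020
    dominance: float = 2.2
    dominance_offset: float = 3.0
    log_sigma: float = 1.0
    n_planted: int = 0
    target_abs_corr: tuple[float, ...] = ()
    planted_signs: tuple[int, ...] = ()
    rwl_means: tuple[float, float] = (18.2, 0.2)  # (PS, NS) group means in %
    rwl_sd: float = 3.0
    n_ps: int = 8
    depth: int = 100_000
    baseline_bmi_mean: float = 43.1
    baseline_bmi_sd: float = 4.0
    dbmi_noise_sd: float = 0.5
    level: str = "genus"
    planted_rank_range: tuple[int, int] = (5, 60)
    outcome_mode: str = "bimodal"  # or "from_planted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_taxa_raw:
            raise ValueError("n_planted exceeds n_taxa_raw")
        if self.n_ps > self.n_patients:
            raise ValueError("n_ps exceeds n_patients")
        if len(self.target_abs_corr) != self.n_planted:
            raise ValueError("target_abs_corr must have one entry per planted taxon")
        if any(not (0.0 <= r <= 1.0) for r in self.target_abs_corr):
            raise ValueError("target_abs_corr entries must lie in [0, 1]")
        if self.planted_signs and len(self.planted_signs) != self.n_planted:
            raise ValueError("planted_signs must have one entry per planted taxon")
        if any(s not in (-1, 1) for s in self.planted_signs):
            raise ValueError("planted_signs entries must be +1 or -1")
        if self.n_planted and self.planted_rank_range[1] > self.n_taxa_raw:
            raise ValueError("planted_rank_range exceeds n_taxa_raw")
        if self.outcome_mode not in ("bimodal", "from_planted"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.outcome_mode == "from_planted":
            if self.n_planted < 1:
                raise ValueError("from_planted outcome mode requires planted taxa")
            if len(set(self.target_abs_corr)) > 1:
                raise ValueError(
                    "from_planted outcome mode supports a single common target correlation"
                )

    @property
    def signs(self) -> tuple[int, ...]:
        return self.planted_signs if self.planted_signs else (1,) * self.n_planted

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("target_abs_corr", "planted_signs", "rwl_means", "planted_rank_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    abundance: AbundanceTable
    outcomes: CohortOutcomes
    planted_taxa: list[tuple[str, float, int]] = field(default_factory=list)
    spec: CohortSpec | None = None

    def __post_init__(self) -> None:
        cols = set(self.abundance.taxon_ids)
        for taxon, _, _ in self.planted_taxa:
            if taxon not in cols:
                raise ValueError(f"planted taxon {taxon!r} missing from abundance table")
        self.outcomes.check_group_consistency(SUCCESS_THRESHOLD)


#: Presumed-misclassification genera; genus-level synthetic tables name three
#: negligible tail taxa after them so the default blacklist drop is exercised.
_BLACKLIST_NAMES = ("Caldicellulosiruptor", "Thermaerobacter", "Thermobacillus")


def _taxon_names(p: int, level: str) -> list[str]:
    prefix = "Genus" if level == "genus" else "Species"
    names = [f"{prefix}{j + 1:04d}" for j in range(p)]
    if level == "genus" and p >= 100:
        names[-3:] = _BLACKLIST_NAMES
    return names


def _outcomes_frame(spec: CohortSpec, rwl: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    group = np.where(rwl >= SUCCESS_THRESHOLD, "PS", "NS")  # labels re-derived from rule
    bmi0 = rng.normal(spec.baseline_bmi_mean, spec.baseline_bmi_sd, n)
    # losing weight lowers BMI: positive RWL maps to negative delta BMI
    dbmi = -(bmi0 / 100.0) * rwl + rng.normal(0.0, spec.dbmi_noise_sd, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(n)],
            "group": group,
            "rwl_percent": rwl,
            "delta_bmi": dbmi,
        }
    )


def _draw_outcomes(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    rwl = np.empty(n)
    rwl[: spec.n_ps] = rng.normal(spec.rwl_means[0], spec.rwl_sd, spec.n_ps)
    rwl[spec.n_ps :] = rng.normal(spec.rwl_means[1], spec.rwl_sd, n - spec.n_ps)
    return _outcomes_frame(spec, rwl, rng)


def _closed_proportions(mu: np.ndarray, sigma: float, z: np.ndarray) -> np.ndarray:
    log_abund = mu[None, :] + sigma * z
    log_abund -= log_abund.max(axis=1, keepdims=True)  # overflow guard
    raw = np.exp(log_abund)
    return raw / raw.sum(axis=1, keepdims=True)


def _planted_residuals(raw: np.ndarray) -> np.ndarray:
    """Antithetic unit-variance residuals for the planted taxa.

    Centering each draw across the k planted taxa (rescaled to unit variance)
    makes the residuals sum to zero, so the outcome lies in the linear span of
    the planted latent abundances: each taxon keeps its marginal target
    correlation while the trio jointly explains the outcome, instead of k
    redundant noisy copies of it.
    """
    k = raw.shape[1]
    if k < 2:
        return raw
    centered = raw - raw.mean(axis=1, keepdims=True)
    return centered * np.sqrt(k / (k - 1))


def _plant(
    z: np.ndarray,
    cols: np.ndarray,
    rhos: np.ndarray,
    signs: np.ndarray,
    y_std: np.ndarray,
    eps: np.ndarray,
) -> np.ndarray:
    z = z.copy()
    resid = _planted_residuals(eps)
    z[:, cols] = signs * (rhos * y_std[:, None] + np.sqrt(1.0 - rhos**2) * resid)
    return z


def _surrogate_outcome(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw outcome values from the cohort's bimodal mixture for calibration."""
    is_ps = rng.random(n) < spec.n_ps / spec.n_patients
    means = np.where(is_ps, spec.rwl_means[0], spec.rwl_means[1])
    return rng.normal(means, spec.rwl_sd)


def _realized_mean_abs_r(
    spec: CohortSpec,
    mu: np.ndarray,
    cols: np.ndarray,
    rhos: np.ndarray,
    signs: np.ndarray,
    rng: np.random.Generator,
    n_rep: int,
    n_cal: int = 400,
) -> np.ndarray:
    """Mean |correlation| of the planted taxa over large replicate draws.

    Calibration targets the population correlation, measured on replicates
    large enough that small-sample bias is negligible; the cohort's own
    sample |r| at n = 15 then scatters around the target (its mean runs a
    few hundredths high because |r| of heavy-tailed closed abundances is
    upward-biased at small n)."""
    n = n_cal
    acc = np.zeros(len(cols))
    for _ in range(n_rep):
        y = _surrogate_outcome(spec, rng, n)
        y_std = (y - y.mean()) / y.std()
        z = rng.standard_normal((n, spec.n_taxa_raw))
        eps = rng.standard_normal((n, len(cols)))
        z = _plant(z, cols, rhos, signs, y_std, eps)
        props = _closed_proportions(mu, spec.log_sigma, z)
        x = props[:, cols]
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        acc += np.abs(xc.T @ yc) / denom
    return acc / n_rep


def _calibrate_rhos(
    spec: CohortSpec,
    mu: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    n_rep: int = 8,
    n_iter: int = 4,
    rho_cap: float = 0.9995,
    shortfall_tol: float = 0.05,
) -> np.ndarray:
    """Find latent correlations whose closed-scale sample correlations hit the targets.

    Damped multiplicative fixed-point iteration on the mean realized |r| over
    replicate cohorts; raises :class:`CalibrationError` when even a
    near-deterministic latent link leaves the realized correlation clearly
    short of the target.
    """
    targets = np.asarray(spec.target_abs_corr, dtype=float)
    signs = np.asarray(spec.signs, dtype=float)
    rhos = targets.copy()
    for _ in range(n_iter):
        realized = _realized_mean_abs_r(spec, mu, cols, rhos, signs, rng, n_rep)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(realized > 1e-12, targets / realized, 1.0)
        rhos = np.clip(rhos * np.clip(scale, 0.5, 2.0), 0.0, rho_cap)
    realized = _realized_mean_abs_r(spec, mu, cols, rhos, signs, rng, n_rep)
    short = (realized < targets - shortfall_tol) & (rhos >= rho_cap - 1e-9)
    if short.any():
        bad = [
            f"target |r|={targets[i]:.3f} (achieved {realized[i]:.3f})"
            for i in np.flatnonzero(short)
        ]
        raise CalibrationError(
            "unattainable target correlation(s) for the chosen noise level: "
            + "; ".join(bad)
        )
    return rhos


def _planted_signal(
    props: np.ndarray, cols: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Standardized signed sum of the planted taxa's standardized proportions."""
    x = props[:, cols]
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    signal = (signs * xs).sum(axis=1)
    return (signal - signal.mean()) / signal.std()


def _measure_from_planted_r(
    spec: CohortSpec,
    mu: np.ndarray,
    cols: np.ndarray,
    signs: np.ndarray,
    tau: float,
    rng: np.random.Generator,
    n_rep: int,
    n_cal: int = 400,
) -> float:
    n = n_cal
    acc = 0.0
    for _ in range(n_rep):
        z = rng.standard_normal((n, spec.n_taxa_raw))
        props = _closed_proportions(mu, spec.log_sigma, z)
        y = _planted_signal(props, cols, signs) + tau * rng.standard_normal(n)
        x = props[:, cols]
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        acc += float(np.mean(np.abs(xc.T @ yc) / denom))
    return acc / n_rep


def _calibrate_tau(
    spec: CohortSpec,
    mu: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    n_rep: int = 8,
    shortfall_tol: float = 0.05,
) -> float:
    """Noise scale for the from-planted outcome hitting the common |r| target."""
    target = spec.target_abs_corr[0]
    signs = np.asarray(spec.signs, dtype=float)
    r0 = _measure_from_planted_r(spec, mu, cols, signs, 0.0, rng, n_rep)
    if r0 < target - shortfall_tol:
        raise CalibrationError(
            f"unattainable target correlation |r|={target:.3f} for a response built "
            f"from {len(cols)} planted taxa (noise-free maximum {r0:.3f})"
        )
    tau = float(np.sqrt(max((r0 / target) ** 2 - 1.0, 0.0)))
    for _ in range(2):  # refine under r(tau) ~ r0 / sqrt(1 + tau^2)
        r_tau = _measure_from_planted_r(spec, mu, cols, signs, tau, rng, n_rep)
        r0_eff = r_tau * np.sqrt(1.0 + tau**2)
        tau = float(np.sqrt(max((r0_eff / target) ** 2 - 1.0, 0.0)))
    return tau


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``spec``.

    Counts come from a log-normal compositional model (power-law decaying
    log-means, shared log-SD) sampled to ``spec.depth`` reads per sample by a
    multinomial.  In the default ``bimodal`` outcome mode, RWL is drawn from
    the two group means and planted taxa are rotated toward it in latent
    space with an empirically calibrated correlation.  In ``from_planted``
    mode the RWL is instead built from the planted taxa themselves (signed
    sum of their standardized proportions plus calibrated noise, mapped to
    the RWL scale), so the planted set jointly determines the outcome and is
    recoverable by sparse linear models.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_taxa_raw
    # offset power law: steep decay without a single mega-dominant taxon,
    # whose log-normal noise would otherwise drive every closure denominator
    mu = -spec.dominance * np.log(np.arange(1, p + 1, dtype=float) + spec.dominance_offset)

    if spec.n_planted:
        lo, hi = spec.planted_rank_range
        cols = rng.choice(np.arange(lo - 1, hi), size=spec.n_planted, replace=False)
    else:
        cols = np.empty(0, dtype=int)

    if spec.outcome_mode == "bimodal":
        outcomes_df = _draw_outcomes(spec, rng)
        rwl = outcomes_df["rwl_percent"].to_numpy()
        z = None
        if spec.n_planted:
            rhos = _calibrate_rhos(spec, mu, cols, rng)
        z = rng.standard_normal((spec.n_patients, p))
        if spec.n_planted:
            y_std = (rwl - rwl.mean()) / rwl.std()
            eps = rng.standard_normal((spec.n_patients, spec.n_planted))
            z = _plant(z, cols, rhos, np.asarray(spec.signs, dtype=float), y_std, eps)
        props = _closed_proportions(mu, spec.log_sigma, z)
    else:  # from_planted
        tau = _calibrate_tau(spec, mu, cols, rng)
        z = rng.standard_normal((spec.n_patients, p))
        props = _closed_proportions(mu, spec.log_sigma, z)
        signs = np.asarray(spec.signs, dtype=float)
        raw = _planted_signal(props, cols, signs) + tau * rng.standard_normal(spec.n_patients)
        raw = (raw - raw.mean()) / raw.std()
        center = float(np.mean(spec.rwl_means))
        scale = float(abs(spec.rwl_means[0] - spec.rwl_means[1])) / 2.0
        rwl = center + scale * raw
        outcomes_df = _outcomes_frame(spec, rwl, rng)

    counts = np.empty_like(props)
    for i in range(spec.n_patients):
        counts[i] = rng.multinomial(spec.depth, props[i])

    taxon_ids = _taxon_names(p, spec.level)
    table = AbundanceTable(
        sample_ids=list(outcomes_df["patient_id"]),
        taxon_ids=taxon_ids,
        values=counts,
        level=spec.level,
        is_proportion=False,
    )
    planted = [
        (taxon_ids[c], float(t), int(s))
        for c, t, s in zip(cols, spec.target_abs_corr, spec.signs)
    ]
    return SyntheticCohort(
        abundance=table,
        outcomes=CohortOutcomes(outcomes_df),
        planted_taxa=planted,
        spec=spec,
    )


def write_cohort(cohort: SyntheticCohort, dir_path: str | Path) -> dict[str, Path]:
    """Write abundance TSV, outcomes CSV and a provenance JSON to ``dir_path``."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / f"abundance_{cohort.abundance.level}.tsv",
        "outcomes": out / "outcomes.csv",
        "provenance": out / "provenance.json",
    }
    df = cohort.abundance.to_dataframe()
    df.index.name = "sample_id"
    # %.17g keeps float64 exactly round-trippable through text
    df.to_csv(paths["abundance"], sep="\t", float_format="%.17g")
    cohort.outcomes.frame.to_csv(paths["outcomes"], index=False, float_format="%.17g")
    provenance = {
        "spec": cohort.spec.to_dict() if cohort.spec is not None else None,
        "seed": cohort.spec.seed if cohort.spec is not None else None,
        "planted_taxa": [
            {"taxon_id": t, "target_abs_corr": r, "sign": s}
            for t, r, s in cohort.planted_taxa
        ],
    }
    paths["provenance"].write_text(json.dumps(provenance, indent=2))
    return paths


def read_cohort(dir_path: str | Path, level: str | None = None) -> SyntheticCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    out = Path(dir_path)
    prov = json.loads((out / "provenance.json").read_text())
    spec = CohortSpec.from_dict(prov["spec"]) if prov.get("spec") else None
    if level is None:
        level = spec.level if spec is not None else "genus"
    table = load_abundance(out / f"abundance_{level}.tsv", level=level, is_proportion=False)
    outcomes = load_outcomes(out / "outcomes.csv")
    planted = [
        (d["taxon_id"], d["target_abs_corr"], d["sign"]) for d in prov["planted_taxa"]
    ]
    return SyntheticCohort(abundance=table, outcomes=outcomes, planted_taxa=planted, spec=spec)
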