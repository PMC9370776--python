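"""Reading abundance/outcome tables and reducing them to predictor matrices.

The raw input is a taxa-by-sample abundance table (counts or proportions) plus
a per-patient outcomes table.  Preparation removes blacklisted taxa, keeps the
most abundant columns, and re-closes rows to proportions over the retained
taxa, reporting the fraction of the original mass that was kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AbundanceTable",
    "CohortOutcomes",
    "PredictorMatrix",
    "DEFAULT_GENUS_BLACKLIST",
    "load_abundance",
    "load_outcomes",
    "drop_blacklisted",
    "reduce_to_top",
]

#: Genera that do not normally occur in the gut microbiome and are treated as
#: likely misclassifications; removed by default from genus-level tables.
DEFAULT_GENUS_BLACKLIST = ("Caldicellulosiruptor", "Thermaerobacter", "Thermobacillus")

#: RWL (%) threshold separating the persistent-success (PS) group from the
#: nonpersistent-success (NS) group.
SUCCESS_THRESHOLD = 10.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """A samples x taxa abundance matrix with a taxonomy-level tag.

    ``values[i, j]`` is the abundance of taxon ``taxon_ids[j]`` in sample
    ``sample_ids[i]``; either raw counts or per-sample proportions
    (``is_proportion``).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    level: str = "genus"
    is_proportion: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("abundance values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.taxon_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.taxon_ids)) != p:
            seen: set[str] = set()
            dups = sorted({t for t in self.taxon_ids if t in seen or seen.add(t)})
            raise ValidationError(f"duplicate taxon IDs: {dups}")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValidationError(
                f"NaN abundance at sample {self.sample_ids[i]!r}, taxon {self.taxon_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r} (value {self.values[i, j]})"
            )
        if self.is_proportion:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("proportion rows must sum to 1 within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions (rows closed to 1)."""
        sums = self.values.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValidationError("cannot close rows: a sample has zero total abundance")
        return self.values / sums

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class CohortOutcomes:
    """Per-patient outcomes: success group, RWL (%) and delta BMI (kg/m^2)."""

    frame: pd.DataFrame  # columns: patient_id, group, rwl_percent, delta_bmi

    REQUIRED = ("patient_id", "group", "rwl_percent", "delta_bmi")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"outcomes table is missing columns: {missing}")
        bad = set(self.frame["group"]) - {"PS", "NS"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return [str(x) for x in self.frame["patient_id"]]

    @property
    def rwl(self) -> np.ndarray:
        return self.frame["rwl_percent"].to_numpy(dtype=float)

    @property
    def delta_bmi(self) -> np.ndarray:
        return self.frame["delta_bmi"].to_numpy(dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    def check_group_consistency(self, threshold: float = SUCCESS_THRESHOLD) -> None:
        """Verify group labels agree with the RWL >= threshold success rule."""
        expected = np.where(self.rwl >= threshold, "PS", "NS")
        mismatch = expected != self.groups
        if mismatch.any():
            ids = [self.patient_ids[i] for i in np.flatnonzero(mismatch)]
            raise ValidationError(
                f"group labels inconsistent with RWL >= {threshold} rule for patients {ids}"
            )


@dataclass
class PredictorMatrix:
    """Reduced n x p proportions matrix used as the regression design source.

    ``coverage`` is the mean (over samples) fraction of the original relative
    abundance retained by the reduction.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    coverage: float = 1.0
    closed: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not (0.0 < self.coverage <= 1.0 + 1e-12):
            raise ValidationError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.closed:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValidationError("closed predictor rows must sum to 1 within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def load_abundance(
    path: str | Path,
    level: str = "genus",
    is_proportion: bool | None = None,
) -> AbundanceTable:
    """Load a sample-by-taxon abundance table from TSV/CSV.

    Rows are samples (first column the sample ID), columns taxa.  Whether the
    body holds counts or proportions is auto-detected from row sums; ambiguous
    tables require an explicit ``is_proportion`` flag.
    """
    df = _read_table(path)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric abundance body in {path}: {exc}") from None
    taxon_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]

    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"NaN abundance at sample {sample_ids[i]!r}, taxon {taxon_ids[j]!r}"
        )
    if is_proportion is None:
        row_sums = values.sum(axis=1)
        if np.allclose(row_sums, 1.0, atol=1e-3):
            is_proportion = True
        elif (row_sums >= 1.5).all():
            is_proportion = False
        else:
            raise ValidationError(
                f"cannot tell counts from proportions in {path} "
                "(row sums neither ~1 nor clearly larger); pass is_proportion explicitly"
            )
    if is_proportion:
        # tolerate small rounding in the file, then hold rows to the strict invariant
        sums = values.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValidationError(f"zero-sum proportion row in {path}")
        values = values / sums
    return AbundanceTable(sample_ids, taxon_ids, values, level=level, is_proportion=is_proportion)


def load_outcomes(path: str | Path, check_groups: bool = True) -> CohortOutcomes:
    """Load the per-patient outcomes CSV (patient_id, group, rwl_percent, delta_bmi)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    outcomes = CohortOutcomes(pd.read_csv(path, float_precision="round_trip"))
    if check_groups:
        outcomes.check_group_consistency()
    return outcomes


def drop_blacklisted(
    table: AbundanceTable, blacklist: tuple[str, ...] | list[str] | None = None
) -> AbundanceTable:
    """Remove blacklisted taxon columns.

    ``blacklist=None`` applies the default: the three presumed-misclassified
    genera for genus-level tables, nothing for species-level tables.  Entries
    absent from the table are ignored with a warning.
    """
    if blacklist is None:
        blacklist = DEFAULT_GENUS_BLACKLIST if table.level == "genus" else ()
    blacklist = tuple(blacklist)
    present = [t for t in blacklist if t in table.taxon_ids]
    absent = [t for t in blacklist if t not in table.taxon_ids]
    if absent:
        warnings.warn(f"blacklist entries not present in table: {absent}", stacklevel=2)
    if not present:
        return table
    keep = [j for j, t in enumerate(table.taxon_ids) if t not in set(present)]
    # dropping columns from a proportion table leaves rows summing below 1
    return replace(
        table,
        taxon_ids=[table.taxon_ids[j] for j in keep],
        values=table.values[:, keep],
        is_proportion=False,
    )


def reduce_to_top(
    table: AbundanceTable,
    n_keep: int,
    statistic: str = "mean",
    reclose: bool = True,
) -> PredictorMatrix:
    """Keep the ``n_keep`` most abundant taxa and re-close rows to proportions.

    "Most abundant" means largest mean relative abundance across samples
    (``statistic="mean"``) or highest prevalence (``statistic="prevalence"``,
    ties by mean).  Ties are broken by taxon ID lexicographic order.  Retained
    columns are ordered by decreasing abundance.  With ``reclose=False`` the
    original relative abundances are kept (rows then no longer sum to 1).
    """
    if n_keep <= 0:
        raise ValueError(f"n_keep must be positive, got {n_keep}")
    if n_keep > table.n_taxa:
        raise ValueError(f"n_keep={n_keep} exceeds table width {table.n_taxa}")
    rel = table.relative_abundance()
    if statistic == "mean":
        score = rel.mean(axis=0)
    elif statistic == "prevalence":
        score = (rel > 0).mean(axis=0) + 1e-12 * rel.mean(axis=0)
    else:
        raise ValueError(f"unknown ordering statistic {statistic!r}")
    order = sorted(range(table.n_taxa), key=lambda j: (-score[j], table.taxon_ids[j]))
    kept = order[:n_keep]
    sub = rel[:, kept]
    per_sample_cov = sub.sum(axis=1)
    coverage = float(per_sample_cov.mean())
    if reclose:
        values = sub / per_sample_cov[:, None]
    else:
        values = sub
    return PredictorMatrix(
        sample_ids=list(table.sample_ids),
        taxon_ids=[table.taxon_ids[j] for j in kept],
        values=values,
        coverage=coverage,
        closed=reclose,
    )
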