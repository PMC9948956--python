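"""Cross-condition summary statistics.

Weighted Pearson correlations and weighted SDs across cell types (weights =
cells sequenced per type, so abundant, precisely-estimated types dominate),
difference-from-overall-residual profiles, washout recovery arithmetic,
qPCR delta-delta-Ct residual quantification, and the dose -> molecules-per-
cell calculator. All reported residual scales are percent (0-100); fractions
are internal only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants, stats

PERCENT_SCALE_FLOOR = 1.5  # values all at or below this look like fractions


@dataclass
class WeightedSeries:
    """Labelled values with positive frequency weights (cells per label)."""

    labels: list[str]
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.labels) == self.values.size == self.weights.size):
            raise ValueError("labels, values and weights must have equal length")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")


@dataclass
class ConditionProfile:
    """Per-cell-type residuals (%) for one condition, and each type's
    difference from the overall (all-cells) residual in percentage points.
    Positive difference = weaker knockdown than bulk tissue."""

    condition: str
    cell_types: list[str]
    residuals: np.ndarray  # percent
    overall: float  # percent
    differences: np.ndarray  # percentage points
    n_cells: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_type": self.cell_types,
                "residual": self.residuals,
                "difference": self.differences,
            }
        )
        if self.n_cells.size:
            df["n_cells"] = self.n_cells
        df["condition"] = self.condition
        return df


@dataclass
class DoseSpec:
    """A dose in grams of an oligo of given molecular weight, distributed
    over n_cells, of which a fraction undergoes productive uptake."""

    dose_mass: float  # grams
    molecular_weight: float  # g/mol
    n_cells: float
    productive_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.dose_mass <= 0 or self.molecular_weight <= 0 or self.n_cells <= 0:
            raise ValueError("dose_mass, molecular_weight and n_cells must be positive")
        if not 0.0 <= self.productive_fraction <= 1.0:
            raise ValueError("productive_fraction must be in [0,1]")


def _normalized_weights(w: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w * n / w.sum()


def weighted_pearson(x, y, w) -> tuple[float, float]:
    """Weighted Pearson correlation and its two-sided p-value.

    Weights are normalised to sum to n (frequency-weight convention); the
    p-value comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom. With equal weights this is the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("nonfinite values")
    w = _normalized_weights(w, n)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    syy = np.sum(w * (y - ym) ** 2)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance")
    rho = float(np.sum(w * (x - xm) * (y - ym)) / math.sqrt(sxx * syy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def weighted_sd(values, w) -> float:
    """Square root of the frequency-weighted unbiased variance, weights
    normalised to sum to n. Equal weights reduce to the sample SD."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    w = _normalized_weights(w, n)
    xm = np.average(x, weights=w)
    return float(math.sqrt(np.sum(w * (x - xm) ** 2) / (n - 1)))


def _looks_like_fractions(values: np.ndarray) -> bool:
    return bool(np.all(values <= PERCENT_SCALE_FLOOR))


def difference_from_overall(
    condition: str,
    cell_types: list[str],
    residuals_percent,
    overall_percent: float,
    n_cells=None,
) -> ConditionProfile:
    """Each cell type's residual (%) minus the overall all-cells residual (%).

    Positive differences mean weaker knockdown than bulk tissue. Inputs
    must be on the percent scale; a profile whose values all sit at or
    below 1.5 is rejected as a likely fraction-scale mix-up.
    """
    residuals = np.asarray(residuals_percent, dtype=float)
    if _looks_like_fractions(residuals) != (overall_percent <= PERCENT_SCALE_FLOOR):
        raise ValueError("scale mismatch: residuals and overall differ in scale")
    if _looks_like_fractions(residuals):
        raise ValueError(
            "residuals look like fractions; supply percent-scale values"
        )
    return ConditionProfile(
        condition=condition,
        cell_types=list(cell_types),
        residuals=residuals,
        overall=float(overall_percent),
        differences=residuals - float(overall_percent),
        n_cells=np.asarray(n_cells if n_cells is not None else [], dtype=float),
    )


def recovery(residual_early_percent: float, residual_late_percent: float) -> float:
    """Washout recovery in percentage points: late minus early residual."""
    return float(residual_late_percent) - float(residual_early_percent)


def ddct_residual(
    q: pd.DataFrame, reference_treatment: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta-delta-Ct relative quantification.

    Technical duplicates (repeated sample ids) are averaged on the Ct scale
    first. Then dCt = ct_target - ct_housekeeping, ddCt = dCt - mean(dCt
    over the reference arm), residual = 2^(-ddCt) * 100%. Returns
    (per_sample, per_arm) tables; the reference arm's residual averages
    100% on the ddCt (log) scale by construction.
    """
    for col in ("sample", "treatment", "ct_target", "ct_housekeeping"):
        if col not in q.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    if q["ct_housekeeping"].isna().any() or q["ct_target"].isna().any():
        raise ValueError("missing Ct values")
    per_sample = (
        q.groupby(["sample", "treatment"], sort=True, observed=True)[
            ["ct_target", "ct_housekeeping"]
        ]
        .mean()
        .reset_index()
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_housekeeping"]
    ref = per_sample[per_sample["treatment"] == reference_treatment]
    if ref.empty:
        raise ValueError(f"no samples in reference arm {reference_treatment!r}")
    ref_mean = ref["dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - ref_mean
    per_sample["residual_percent"] = 100.0 * 2.0 ** (-per_sample["ddct"])
    per_arm = (
        per_sample.groupby("treatment", sort=True, observed=True)
        .agg(
            residual_percent=("residual_percent", "mean"),
            n=("residual_percent", "size"),
        )
        .reset_index()
    )
    return per_sample, per_arm


def molecules_per_cell(d: DoseSpec) -> tuple[float, float, float]:
    """Dose arithmetic: total molecules in the dose, molecules per cell,
    and productively-taken-up molecules per cell."""
    total = d.dose_mass / d.molecular_weight * constants.Avogadro
    per_cell = total / d.n_cells
    return total, per_cell, per_cell * d.productive_fraction


def pairwise_weighted_correlations(
    values: pd.DataFrame, weights: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlogram matrices: weighted Pearson rho and p for every pair of
    condition columns, over cell types (rows) present in both, weighting
    each cell type by the mean of the two conditions' cell counts."""
    conds = list(values.columns)
    rho = pd.DataFrame(np.eye(len(conds)), index=conds, columns=conds)
    pval = pd.DataFrame(np.zeros((len(conds), len(conds))), index=conds, columns=conds)
    for i, a in enumerate(conds):
        for j, b in enumerate(conds):
            if j <= i:
                continue
            shared = values[[a, b]].dropna().index
            shared = [s for s in shared if s in weights.index]
            if len(shared) < 3:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                pval.loc[a, b] = pval.loc[b, a] = np.nan
                continue
            w = 0.5 * (weights.loc[shared, a] + weights.loc[shared, b])
            r, p = weighted_pearson(
                values.loc[shared, a], values.loc[shared, b], w
            )
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval
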