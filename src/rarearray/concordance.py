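"""Array-vs-reference MAF concordance filtering on a log2-ratio scale.

For every variant with both array and reference MAF above zero,
``r = log2(array_maf / ref_maf)``. Variants with ``r`` above ``t_upper`` or
below ``t_lower`` are excluded as low-concordance probesets; variants where
either MAF is zero are *indeterminate* (the ratio is undefined at the
resolution of either cohort) and are routed to experimental validation
rather than excluded. A linear regression of log2 array MAF on log2
reference MAF over the retained variants provides the slope / R²
diagnostics and drives the optional threshold grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from rarearray.types import AB, BB, NOCALL, GenotypeMatrix

__all__ = [
    "DEFAULT_T_UPPER",
    "DEFAULT_T_LOWER",
    "MAF_BIN_EDGES",
    "RegressionDiagnostics",
    "compute_array_maf",
    "filter_by_concordance",
    "optimize_thresholds",
]

DEFAULT_T_UPPER = 1.72
DEFAULT_T_LOWER = -2.0

# reporting bins on the reference MAF (fractions): (0, 0.01%], ..., (0.5%, 1%]
MAF_BIN_EDGES = (0.0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2)
MAF_BIN_LABELS = (
    "(0%,0.01%]",
    "(0.01%,0.05%]",
    "(0.05%,0.1%]",
    "(0.1%,0.5%]",
    "(0.5%,1%]",
)


def compute_array_maf(final: GenotypeMatrix) -> pd.DataFrame:
    """Minor allele frequency per variant from consolidated calls.

    MAF = (n_AB + 2 * n_BB) / (2 * n_called); NoCalls are excluded from the
    denominator. Variants with zero called samples get NaN and
    ``defined=False``.
    """
    c = final.calls.to_numpy()
    n_ab = (c == AB).sum(axis=1)
    n_bb = (c == BB).sum(axis=1)
    n_called = (c != NOCALL).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n_called > 0, (n_ab + 2.0 * n_bb) / (2.0 * n_called), np.nan)
    return pd.DataFrame(
        {
            "variant_id": final.probesets,
            "array_maf": maf,
            "n_called": n_called,
            "defined": n_called > 0,
        }
    ).set_index("variant_id")


@dataclass
class RegressionDiagnostics:
    """Linear fit of log2 array MAF on log2 reference MAF, retained set only."""

    slope: float
    intercept: float
    r_squared: float
    n_retained: int
    n_excluded: int
    n_indeterminate: int
    bin_exclusion: pd.DataFrame = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "n_indeterminate": self.n_indeterminate,
        }


def _regress(log_ref: np.ndarray, log_array: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, R²); NaNs when underdetermined."""
    if len(log_ref) < 3 or np.ptp(log_ref) == 0:
        return np.nan, np.nan, np.nan
    fit = stats.linregress(log_ref, log_array)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def filter_by_concordance(
    array_mafs: pd.DataFrame | pd.Series,
    ref_mafs: pd.DataFrame | pd.Series,
    t_upper: float = DEFAULT_T_UPPER,
    t_lower: float = DEFAULT_T_LOWER,
) -> tuple[pd.DataFrame, RegressionDiagnostics]:
    """Apply the log2-ratio concordance filter.

    Parameters
    ----------
    array_mafs
        Output of :func:`compute_array_maf`, or a Series of MAFs keyed by
        variant.
    ref_mafs
        Series of reference MAFs keyed by variant, or a frame with
        ``variant_id`` / ``ref_maf`` columns.

    Returns the per-variant result table (array_maf, ref_maf, log2_ratio,
    verdict, thresholds) and the retained-set regression diagnostics with
    per-MAF-bin exclusion rates.
    """
    if t_lower >= t_upper:
        raise ValueError(f"t_lower={t_lower} must be below t_upper={t_upper}")
    array = _as_maf_series(array_mafs, "array_maf")
    ref = _as_maf_series(ref_mafs, "ref_maf")
    common = array.index.intersection(ref.index)
    if len(common) == 0:
        raise ValueError("array and reference MAF tables share no variants")
    array = array.loc[common]
    ref = ref.loc[common]

    a = array.to_numpy(float)
    f = ref.to_numpy(float)
    determinate = np.isfinite(a) & np.isfinite(f) & (a > 0) & (f > 0)
    r = np.full(len(common), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r[determinate] = np.log2(a[determinate] / f[determinate])
    excluded = determinate & ((r > t_upper) | (r < t_lower))
    verdict = np.where(
        ~determinate, "indeterminate", np.where(excluded, "excluded", "retained")
    )

    results = pd.DataFrame(
        {
            "array_maf": a,
            "ref_maf": f,
            "log2_ratio": r,
            "verdict": verdict,
            "t_upper": t_upper,
            "t_lower": t_lower,
        },
        index=common.rename("variant_id"),
    )

    retained = verdict == "retained"
    slope, intercept, r2 = _regress(np.log2(f[retained]), np.log2(a[retained]))

    bins = pd.cut(f, MAF_BIN_EDGES, labels=MAF_BIN_LABELS)
    per_bin = (
        pd.DataFrame({"bin": bins, "verdict": verdict})
        .groupby("bin", observed=False)["verdict"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["retained", "excluded", "indeterminate"], fill_value=0)
    )
    denom = per_bin["retained"] + per_bin["excluded"]
    per_bin["exclusion_rate"] = np.where(denom > 0, per_bin["excluded"] / denom, np.nan)

    diagnostics = RegressionDiagnostics(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_retained=int(retained.sum()),
        n_excluded=int(excluded.sum()),
        n_indeterminate=int((~determinate).sum()),
        bin_exclusion=per_bin,
    )
    return results, diagnostics


def _as_maf_series(table, column: str) -> pd.Series:
    if isinstance(table, pd.Series):
        return table.astype(float)
    frame = table
    if "variant_id" in frame.columns:
        frame = frame.set_index("variant_id")
    if column not in frame.columns:
        raise ValueError(f"MAF table lacks a {column!r} column")
    return frame[column].astype(float)


def optimize_thresholds(
    array_mafs,
    ref_mafs,
    upper_grid=None,
    lower_grid=None,
) -> tuple[float, float, pd.DataFrame]:
    """Grid search for the threshold pair maximizing retained-set R².

    Ties are broken toward the widest interval (fewest exclusions). Returns
    the chosen (t_upper, t_lower) and the full R² surface. This never
    overrides the published default thresholds implicitly — callers opt in.
    """
    if upper_grid is None:
        upper_grid = np.round(np.arange(0.5, 4.01, 0.25), 4)
    if lower_grid is None:
        lower_grid = np.round(np.arange(-4.0, -0.49, 0.25), 4)
    rows = []
    best = None
    for t_up in upper_grid:
        for t_lo in lower_grid:
            if t_lo >= t_up:
                continue
            results, diag = filter_by_concordance(array_mafs, ref_mafs, t_up, t_lo)
            rows.append(
                {
                    "t_upper": float(t_up),
                    "t_lower": float(t_lo),
                    "r_squared": diag.r_squared,
                    "n_excluded": diag.n_excluded,
                }
            )
            if np.isnan(diag.r_squared):
                continue
            key = (diag.r_squared, float(t_up) - float(t_lo))
            if best is None or key > best[0]:
                best = (key, float(t_up), float(t_lo))
    surface = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no threshold pair yielded a defined R²")
    return best[1], best[2], surface
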