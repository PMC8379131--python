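"""Longitudinal cohort statistics.

Implements the study-shaped analysis: follow-up/baseline ratios
annualized linearly to 365.25 days, a Pearson correlation matrix of the
three baseline functional means against eight reference columns
(baseline value and annualized ratio of FVC%, DLCO%, lung volume, mean
lung density), and the NAA-vs-HAA paired t test. Missing values are
handled by pairwise deletion, so DLCO cells run at reduced n. No
multiple-testing correction is applied by default.

Pearson R and the paired t statistic are coded directly from the moment
formulas (not delegated to scipy.stats test functions) so that tests can
cross-check them against an independent implementation; only the t-
distribution tail probability comes from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import DegenerateInputError, UsageError

DAYS_PER_YEAR = 365.25

FUNCTIONAL_COLUMNS = {
    "ventilation": "ventilation_b",
    "perfusion": "perfusion_b",
    "late_enhancement": "late_enhancement_b",
}

# (row label, baseline column, follow-up column); None marks baseline-only cells
REFERENCE_SPECS = [
    ("FVC% b", "fvc_pct_b", None),
    ("FVC% f/b", "fvc_pct_b", "fvc_pct_f"),
    ("DLCO% b", "dlco_pct_b", None),
    ("DLCO% f/b", "dlco_pct_b", "dlco_pct_f"),
    ("Lung volume b", "lung_volume_ml_b", None),
    ("Lung volume f/b", "lung_volume_ml_b", "lung_volume_ml_f"),
    ("Mean lung density b", "lung_density_hu_b", None),
    ("Mean lung density f/b", "lung_density_hu_b", "lung_density_hu_f"),
]


@dataclass
class CorrelationResult:
    R: float
    p: float
    n: int

    @property
    def significant_05(self) -> bool:
        return self.p <= 0.05

    @property
    def significant_01(self) -> bool:
        return self.p <= 0.01


def annualize_ratio(baseline: float, followup: float, interval_days: float) -> float:
    """Follow-up/baseline ratio normalized linearly to a 1-year interval."""
    if interval_days <= 0:
        raise UsageError(f"interval must be positive, got {interval_days}")
    if baseline == 0:
        raise UsageError("baseline value must be nonzero")
    ratio = followup / baseline
    return 1.0 + (ratio - 1.0) * (DAYS_PER_YEAR / interval_days)


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p value.

    Pairs with a missing value in either vector are dropped first.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    sxx = float(np.dot(xd, xd))
    syy = float(np.dot(yd, yd))
    # near-constant guard: float jitter on a constant column must not
    # masquerade as variance
    x_scale = max(float(np.abs(x).max()), 1.0)
    y_scale = max(float(np.abs(y).max()), 1.0)
    if np.sqrt(sxx / n) < 1e-9 * x_scale or np.sqrt(syy / n) < 1e-9 * y_scale:
        raise DegenerateInputError("zero variance in an input vector")
    r = float(np.dot(xd, yd) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(R=r, p=p, n=n)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t test (n-1 df, two-sided) on equal-length vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise UsageError("a and b must be 1D vectors of equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 2:
        raise DegenerateInputError(f"need >= 2 complete pairs, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * _stats.t.sf(abs(t), df=n - 1))
    return t, p


def _reference_column(cohort: pd.DataFrame, base_col: str, follow_col: str | None):
    base = pd.to_numeric(cohort[base_col], errors="coerce").to_numpy(dtype=float)
    if follow_col is None:
        return base
    follow = pd.to_numeric(cohort[follow_col], errors="coerce").to_numpy(dtype=float)
    interval = pd.to_numeric(cohort["interval_days"], errors="coerce").to_numpy(dtype=float)
    out = np.full(base.shape, np.nan)
    for i in range(base.size):
        if (
            np.isfinite(base[i]) and np.isfinite(follow[i])
            and np.isfinite(interval[i]) and base[i] != 0 and interval[i] > 0
        ):
            out[i] = annualize_ratio(base[i], follow[i], interval[i])
    return out


def correlation_table(cohort: pd.DataFrame, min_n: int = 4) -> pd.DataFrame:
    """3 functional parameters x 8 reference columns of CorrelationResults.

    Returns a long-format DataFrame (reference, parameter, R, p, n,
    sig_05, sig_01, available). Cells with fewer than ``min_n`` complete
    pairs or a degenerate reference are marked unavailable rather than
    aborting the whole table.
    """
    rows = []
    for ref_name, base_col, follow_col in REFERENCE_SPECS:
        ref = _reference_column(cohort, base_col, follow_col)
        for param, col in FUNCTIONAL_COLUMNS.items():
            vals = pd.to_numeric(cohort[col], errors="coerce").to_numpy(dtype=float)
            keep = np.isfinite(ref) & np.isfinite(vals)
            cell = {
                "reference": ref_name,
                "parameter": param,
                "R": np.nan,
                "p": np.nan,
                "n": int(keep.sum()),
                "sig_05": False,
                "sig_01": False,
                "available": False,
            }
            if keep.sum() >= min_n:
                try:
                    res = pearson(vals[keep], ref[keep])
                except DegenerateInputError:
                    pass
                else:
                    cell.update(
                        R=res.R, p=res.p, n=res.n,
                        sig_05=res.significant_05, sig_01=res.significant_01,
                        available=True,
                    )
            rows.append(cell)
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format table into the 8x3 R-value matrix."""
    return table.pivot(index="reference", columns="parameter", values="R").reindex(
        [name for name, _, _ in REFERENCE_SPECS]
    )
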