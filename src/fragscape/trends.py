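"""Time-series change statistics, driver correlations and map accuracy.

Covers the tabular side of a fragmentation study: per-interval annual loss
of the focal class, bivariate Pearson correlations between socioeconomic
factors and landscape responses, and confusion-matrix accuracy (overall
accuracy and Cohen's kappa) of the underlying classified maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AreaTimeSeries:
    """Per-year focal-class and total areas (km^2), strictly increasing years."""

    years: np.ndarray
    total_km2: np.ndarray
    farmland_km2: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.total_km2 = np.asarray(self.total_km2, dtype=float)
        self.farmland_km2 = np.asarray(self.farmland_km2, dtype=float)
        if not (self.years.size == self.total_km2.size == self.farmland_km2.size):
            raise ValueError("year/area columns must have equal length")
        if np.unique(self.years).size != self.years.size:
            raise ValueError("duplicate years")
        if not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if (self.total_km2 <= 0).any() or (self.farmland_km2 <= 0).any():
            raise ValueError("areas must be positive")
        if (self.farmland_km2 > self.total_km2).any():
            raise ValueError("farmland area cannot exceed total area")

    @classmethod
    def from_csv(cls, path) -> "AreaTimeSeries":
        df = pd.read_csv(path)
        return cls(
            years=df["year"].to_numpy(),
            total_km2=df["total_area_km2"].to_numpy(),
            farmland_km2=df["farmland_area_km2"].to_numpy(),
        )


def round_report(x: float, digits: int = 2) -> float:
    """Rounding used only at the reporting boundary.

    Inputs carry at most 2-decimal precision, so intermediate float error is
    first scrubbed by quantizing to 8 decimals; exact ties at the reporting
    precision then round toward zero, the convention the published change
    tables follow (an exact quotient of -193.095 prints as -193.09).
    """
    scrubbed = Decimal(repr(float(x))).quantize(Decimal("1e-8"), rounding=ROUND_HALF_EVEN)
    return float(scrubbed.quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_DOWN))


def change_statistics(ts: AreaTimeSeries) -> pd.DataFrame:
    """Per-year proportion and per-interval average annual change.

    For each consecutive pair (t1, t2): annual change
    = (area2 - area1) / (t2 - t1) in km^2/yr (losses negative) and annual
    rate = change / area1 * 100 in %/yr (interval-start denominator).
    Values are kept at full precision; round at report time.
    """
    if ts.years.size < 2:
        raise ValueError("change statistics need at least 2 rows")
    proportion = ts.farmland_km2 / ts.total_km2 * 100.0
    decrement = np.full(ts.years.size, np.nan)
    rate = np.full(ts.years.size, np.nan)
    for i in range(1, ts.years.size):
        span = ts.years[i] - ts.years[i - 1]
        decrement[i] = (ts.farmland_km2[i] - ts.farmland_km2[i - 1]) / span
        rate[i] = decrement[i] / ts.farmland_km2[i - 1] * 100.0
    return pd.DataFrame(
        {
            "year": ts.years,
            "total_area_km2": ts.total_km2,
            "farmland_area_km2": ts.farmland_km2,
            "proportion_pct": proportion,
            "annual_decrement_km2_yr": decrement,
            "annual_decrement_rate_pct_yr": rate,
        }
    )


def rounded_report(stats_df: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Reporting-boundary copy rounded to ``digits`` decimals."""
    out = stats_df.copy()
    for col in out.columns:
        if col == "year":
            continue
        out[col] = [
            np.nan if pd.isna(v) else round_report(float(v), digits) for v in out[col]
        ]
    return out


@dataclass
class FactorSeries:
    """Per-year socioeconomic factor values (GDP, GAP, PGAP, TP, AP, PAP...).

    When both a quantity and its proportion are present (GAP/GDP -> PGAP,
    AP/TP -> PAP) their consistency is checked within rounding and a warning
    is issued on disagreement.
    """

    table: pd.DataFrame  # indexed by year

    def __post_init__(self) -> None:
        if "year" in self.table.columns:
            self.table = self.table.set_index("year")
        for num, den, pct in (("GAP", "GDP", "PGAP"), ("AP", "TP", "PAP")):
            cols = self.table.columns
            if num in cols and den in cols and pct in cols:
                implied = self.table[num] / self.table[den] * 100.0
                if not np.allclose(implied, self.table[pct], atol=0.5):
                    warnings.warn(
                        f"{pct} disagrees with {num}/{den}*100 beyond rounding",
                        stacklevel=2,
                    )

    @classmethod
    def from_csv(cls, path) -> "FactorSeries":
        return cls(pd.read_csv(path))


def pearson_matrix(
    factors: pd.DataFrame | FactorSeries,
    responses: pd.DataFrame,
    mask_nonsignificant: bool = False,
) -> pd.DataFrame:
    """Bivariate Pearson correlations between factor and response columns.

    Returns a long-form frame with r, the two-tailed p (t-distribution,
    n - 2 df), the pair n, and significance flags '*' (0.05) / '**' (0.01).
    Zero-variance pairs are reported with r = NaN, not r = 0.  With
    ``mask_nonsignificant`` the r of non-significant pairs is blanked
    (NaN), mimicking report tables that print only significant entries.
    """
    if isinstance(factors, FactorSeries):
        factors = factors.table
    if "year" in factors.columns:
        factors = factors.set_index("year")
    if "year" in responses.columns:
        responses = responses.set_index("year")
    rows = []
    for f in factors.columns:
        for rcol in responses.columns:
            pair = pd.concat([factors[f], responses[rcol]], axis=1, join="inner").dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(f"pair ({f}, {rcol}) has n={n} < 3")
            x, y = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            flag = ""
            if np.isfinite(p):
                if p < 0.01:
                    flag = "**"
                elif p < 0.05:
                    flag = "*"
            r_out = r
            if mask_nonsignificant and flag == "" and np.isfinite(r):
                r_out = np.nan
            rows.append({"factor": f, "response": rcol, "r": r_out, "p": p, "n": n, "sig": flag})
    return pd.DataFrame(rows)


def accuracy_kappa(cm: np.ndarray) -> tuple[float, float]:
    """Overall accuracy and Cohen's kappa of a confusion matrix
    (rows = reference, columns = predicted).

    kappa = (p_o - p_e) / (1 - p_e) with p_e = sum_i row_i * col_i / total^2.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if np.isclose(p_e, 1.0):
        raise ValueError("kappa undefined: expected agreement is 1")
    return float(p_o), float((p_o - p_e) / (1.0 - p_e))
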