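"""Time-series regression, log fold-change series and parameter
correlation matrices (complexity vs stability, parameters vs external
series such as pathway enrichment)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_vs_time(series: pd.Series | dict) -> RegressionResult:
    """OLS of a per-month statistic on month, with two-sided slope p."""
    s = pd.Series(series).dropna().sort_index()
    if len(s) < 3:
        raise AnalysisError("regression needs at least three non-missing points")
    t = s.index.to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    fit = stats.linregress(t, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 0.0
    p = float(fit.pvalue) if np.ptp(y) > 0 else 1.0
    return RegressionResult(float(fit.slope), float(fit.intercept), r2, p, len(s))


def log_fc(series_a, series_c, base: float = 2.0) -> pd.Series:
    """Per-month log_base(A / C); undefined months become NaN with a warning."""
    a = pd.Series(series_a).astype(float)
    c = pd.Series(series_c).astype(float)
    months = a.index.intersection(c.index)
    if len(months) == 0:
        raise AnalysisError("no overlapping months between the two series")
    out = {}
    for m in months:
        if a[m] > 0 and c[m] > 0:
            out[m] = np.log(a[m] / c[m]) / np.log(base)
        else:
            logger.warning("logFC undefined at month %s (non-positive value)", m)
            out[m] = np.nan
    return pd.Series(out).sort_index()


def correlate_parameters(
    x_table: pd.DataFrame,
    y_table: pd.DataFrame | None = None,
    method: str = "spearman",
    alpha: float = 0.05,
    min_pairs: int = 4,
    adjust: bool = False,
) -> pd.DataFrame:
    """All-pairs correlation between columns of two observation tables.

    Tables are aligned on their index (observations, e.g. months). Each
    cell reports r, two-sided p, the paired-n used, and a significance
    flag at ``alpha``; pairs with fewer than ``min_pairs`` complete
    observations or a zero-variance series are NaN. Optional
    Benjamini-Hochberg adjustment across cells.
    """
    if method not in ("spearman", "pearson"):
        raise AnalysisError(f"unknown correlation method {method!r}")
    if y_table is None:
        y_table = x_table
    common = x_table.index.intersection(y_table.index)
    rows = []
    for xc in x_table.columns:
        for yc in y_table.columns:
            x = x_table.loc[common, xc].astype(float)
            y = y_table.loc[common, yc].astype(float)
            ok = x.notna() & y.notna()
            r = p = np.nan
            n = int(ok.sum())
            if n >= min_pairs and x[ok].nunique() > 1 and y[ok].nunique() > 1:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if method == "spearman":
                        r, p = stats.spearmanr(x[ok], y[ok])
                    else:
                        r, p = stats.pearsonr(x[ok], y[ok])
            else:
                logger.warning("correlation undefined for (%s, %s)", xc, yc)
            rows.append({"x": xc, "y": yc, "method": method,
                         "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q = p[ok]
    m = q.size
    order = np.argsort(q)
    ranked = q[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    adj[ok] = vals
    return adj
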