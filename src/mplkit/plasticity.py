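"""Methylation plasticity (MPL): per-site spread of beta values across samples.

Plasticity is the variability of a site's methylation level across the
samples of a dataset. It is scored by one of four spread measures:

* ``iqr`` — quantile range Q75-Q25, the default MPL score (robust, and half
  the data lies outside the range, so variability has strong sample support);
* ``q95_q5`` — quantile range Q95-Q5 (wider, 10% of data outside);
* ``sd`` — sample standard deviation (n-1 denominator);
* ``range`` — extreme difference max-min (absolute plasticity; a single
  outlier can carry it, so no sample support).

Quantiles use linear interpolation of order statistics (type 7); the
five-number summary uses Tukey hinges, which differ from type-7 quartiles
for some n — both are reported.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, InvalidParameterError, UndefinedCorrelationError
from .io import BetaMatrix

__all__ = ["MPL_METHODS", "PlasticitySummary", "fivenum", "summarize_site",
           "mpl_score", "high_plasticity_sites", "measure_correlation",
           "plasticity_table"]

MPL_METHODS = ("iqr", "q95_q5", "sd", "range")


def fivenum(values: Sequence[float] | np.ndarray) -> tuple[float, float, float, float, float]:
    """Tukey five-number summary (min, lower hinge, median, upper hinge, max).

    Hinge rule: with x sorted and ``n4 = floor((n + 3) / 2) / 2``, the five
    depths are ``1, n4, (n+1)/2, n+1-n4, n`` and half-integer depths average
    the two neighbouring order statistics.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise InvalidInputError("fivenum of empty input")
    n4 = np.floor((n + 3) / 2) / 2
    depths = np.array([1.0, n4, (n + 1) / 2.0, n + 1 - n4, float(n)])
    lo = np.floor(depths).astype(int) - 1
    hi = np.ceil(depths).astype(int) - 1
    five = 0.5 * (x[lo] + x[hi])
    return tuple(float(v) for v in five)  # type: ignore[return-value]


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


@dataclasses.dataclass
class PlasticitySummary:
    """Distribution summary of one site: fivenum, mean, SD and spread measures."""

    site_id: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float
    sd: float
    iqr: float
    q95_q5: float
    range: float

    def score(self, method: str = "iqr") -> float:
        if method not in MPL_METHODS:
            raise InvalidParameterError(f"unknown MPL method {method!r}")
        return getattr(self, method)


def summarize_site(values, site_id: str = "") -> PlasticitySummary:
    """Fivenum + mean/SD + the three spread measures for one site.

    The hinges come from Tukey's rule; IQR and Q95-Q5 use type-7
    (linearly interpolated) quantiles; SD uses the n-1 denominator and is
    0 for a single value.
    """
    arr = _clean(values)
    if arr.size == 0:
        raise InvalidInputError("summarize_site needs at least one value")
    mn, q1, med, q3, mx = fivenum(arr)
    q5, q25, q75, q95 = np.quantile(arr, [0.05, 0.25, 0.75, 0.95])
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return PlasticitySummary(
        site_id=site_id, n=int(arr.size),
        min=mn, q1=q1, median=med, q3=q3, max=mx,
        mean=float(arr.mean()), sd=sd,
        iqr=float(q75 - q25), q95_q5=float(q95 - q5), range=float(mx - mn),
    )


def mpl_score(values, method: str = "iqr") -> float:
    """MPL score of one site: the selected spread measure (default IQR)."""
    if method not in MPL_METHODS:
        raise InvalidParameterError(f"unknown MPL method {method!r}; use one of {MPL_METHODS}")
    arr = _clean(values)
    if arr.size < 2:
        raise InvalidInputError("MPL score needs at least 2 values")
    return summarize_site(arr).score(method)


def plasticity_table(m: BetaMatrix, method: str = "iqr") -> pd.DataFrame:
    """Per-site summary table with the chosen MPL score in column SCORE.

    Sites with fewer than 2 non-missing values receive no score and are
    omitted; their count is in ``df.attrs['n_unscored']``.
    """
    if method not in MPL_METHODS:
        raise InvalidParameterError(f"unknown MPL method {method!r}")
    rows, unscored = [], 0
    for site in m.site_ids:
        vals = m.site_values(site)
        if vals.size < 2:
            unscored += 1
            continue
        s = summarize_site(vals, site_id=site)
        rows.append({
            "SITE": s.site_id, "N": s.n, "MIN": s.min, "Q1": s.q1,
            "MEDIAN": s.median, "Q3": s.q3, "MAX": s.max, "MEAN": s.mean,
            "SD": s.sd, "IQR": s.iqr, "Q95_Q5": s.q95_q5, "RANGE": s.range,
            "SCORE": s.score(method),
        })
    cols = ["SITE", "N", "MIN", "Q1", "MEDIAN", "Q3", "MAX", "MEAN", "SD",
            "IQR", "Q95_Q5", "RANGE", "SCORE"]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["n_unscored"] = unscored
    df.attrs["method"] = method
    return df


def high_plasticity_sites(m: BetaMatrix, threshold: float, method: str = "iqr") -> pd.DataFrame:
    """Sites with MPL score >= threshold, sorted by descending score.

    Ties broken by site ID (lexicographic), so the ranking is deterministic.
    """
    if not 0 <= threshold <= 1:
        raise InvalidParameterError("threshold must lie in [0, 1]")
    df = plasticity_table(m, method=method)
    df = df[df["SCORE"] >= threshold]
    df = df.sort_values(["SCORE", "SITE"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def measure_correlation(m: BetaMatrix, method_a: str, method_b: str) -> float:
    """Pearson correlation of per-site MPL scores under two measures."""
    df = plasticity_table(m, method="iqr")
    if len(df) < 3:
        raise InvalidInputError("need at least 3 scored sites for a correlation")
    col = {"iqr": "IQR", "q95_q5": "Q95_Q5", "sd": "SD", "range": "RANGE"}
    for meth in (method_a, method_b):
        if meth not in col:
            raise InvalidParameterError(f"unknown MPL method {meth!r}")
    a = df[col[method_a]].to_numpy()
    b = df[col[method_b]].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("a score vector has zero variance")
    return float(stats.pearsonr(a, b).statistic)
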