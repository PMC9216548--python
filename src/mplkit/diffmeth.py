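"""Differential methylation between two sample groups.

Per shared site, a two-sided Mann-Whitney U test (Wilcoxon rank-sum)
compares the beta-value distributions of the groups; p-values are adjusted
for the number of sites by Bonferroni (family-wise error) and
Benjamini-Hochberg (false discovery rate). The effect size reported is the
median difference, and sites flipping tendency class between the groups
(MTS <-> UTS) are flagged as inversions — the strongest form of
differential methylation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientSamplesError, InvalidInputError, InvalidParameterError
from .io import BetaMatrix
from .tendency import classify_tendency, tendency_inversion

__all__ = ["mann_whitney", "bonferroni_threshold", "adjust_pvalues",
           "differential_table"]

#: Largest per-group size at which ``mode='auto'`` uses exact enumeration.
EXACT_N_MAX = 25


def mann_whitney(values_a, values_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first group, p).

    ``mode='exact'`` enumerates the null U distribution; ``'normal'`` uses
    the tie-corrected normal approximation with continuity correction;
    ``'auto'`` picks exact when both groups have at most 25 values and the
    pooled data has no ties, else normal. Ranks use midranks for ties.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups need at least one value")
    if mode == "auto":
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (a.size <= EXACT_N_MAX and b.size <= EXACT_N_MAX
                             and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "normal":
        method = "asymptotic"
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha_original: float, n_tests: int) -> float:
    """Corrected per-test significance level: alpha / number of tests."""
    if not 0 < alpha_original <= 1:
        raise InvalidParameterError("alpha_original must lie in (0, 1]")
    if n_tests < 1:
        raise InvalidParameterError("n_tests must be >= 1")
    return alpha_original / n_tests


def adjust_pvalues(p_values: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment, output order matching input order.

    ``bonferroni``: min(1, p * n). ``bh``: Benjamini-Hochberg step-up with
    the monotone cumulative minimum taken from the largest rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise InvalidParameterError(f"unknown adjustment method {method!r}")


def differential_table(
    m: BetaMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    min_n: int = 4,
    min_abs_median_diff: float = 0.0,
    mode: str = "auto",
) -> pd.DataFrame:
    """Per-site differential methylation between two sample groups.

    For every site shared by both groups (after dropping per-site missing
    values) the table holds the U statistic, raw and adjusted p-values, the
    median difference (group B minus group A) and a tendency-inversion
    flag. Sorted by BH-adjusted p, then by descending absolute median
    difference. ``min_abs_median_diff`` optionally filters the output on
    effect size (default 0 = off).

    Columns: SITE, N_A, N_B, U, P, P_BONF, P_BH, MEDIAN_DIFF, INVERTED.
    """
    sub_a = m.select_samples(list(group_a))
    sub_b = m.select_samples(list(group_b))
    rows = []
    for site in m.site_ids:
        va = sub_a.site_values(site)
        vb = sub_b.site_values(site)
        if va.size == 0 or vb.size == 0:
            continue
        u, p = mann_whitney(va, vb, mode=mode)
        inverted = False
        if va.size >= min_n and vb.size >= min_n:
            try:
                call_a = classify_tendency(va, alpha=alpha, min_n=min_n, site_id=site)
                call_b = classify_tendency(vb, alpha=alpha, min_n=min_n, site_id=site)
                inverted = tendency_inversion(call_a, call_b)
            except InsufficientSamplesError:  # pragma: no cover - guarded above
                pass
        rows.append({
            "SITE": site, "N_A": int(va.size), "N_B": int(vb.size),
            "U": u, "P": p,
            "MEDIAN_DIFF": float(np.median(vb) - np.median(va)),
            "INVERTED": inverted,
        })
    if not rows:
        warnings.warn("no shared sites between the two groups", stacklevel=2)
        return pd.DataFrame(columns=["SITE", "N_A", "N_B", "U", "P", "P_BONF",
                                     "P_BH", "MEDIAN_DIFF", "INVERTED"])
    df = pd.DataFrame(rows)
    df["P_BONF"] = adjust_pvalues(df["P"].to_numpy(), "bonferroni")
    df["P_BH"] = adjust_pvalues(df["P"].to_numpy(), "bh")
    df = df[["SITE", "N_A", "N_B", "U", "P", "P_BONF", "P_BH",
             "MEDIAN_DIFF", "INVERTED"]]
    if min_abs_median_diff > 0:
        df = df[df["MEDIAN_DIFF"].abs() >= min_abs_median_diff]
    df["_absd"] = -df["MEDIAN_DIFF"].abs()
    df = df.sort_values(["P_BH", "_absd", "SITE"], kind="mergesort").drop(columns="_absd")
    return df.reset_index(drop=True)
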