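"""Methylation tendency classification: MTS / UTS / NTS.

A beta value of 0.5 marks balanced methylated/unmethylated probe signal, so
the counts of samples in [0, 0.5) versus (0.5, 1] summarise whether a site
tends to be unmethylated or methylated across a sample population. A
one-degree-of-freedom chi-square goodness-of-fit test against equal
expected counts decides whether the imbalance is significant:

* MTS (methylation-tendency site): p <= alpha and more values above 0.5;
* UTS (unmethylation-tendency site): p <= alpha and more values below 0.5;
* NTS (nonbiased / dual-tendency site): p > alpha.

Values exactly equal to 0.5 belong to neither interval and are excluded
from both counts. The strict variant requires every single value to fall on
one side. A site switching between MTS and UTS across conditions (a
tendency inversion) marks strong differential methylation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientSamplesError, InvalidInputError
from .io import BetaMatrix, groups_from_sheet

__all__ = ["TendencyCall", "classify_tendency", "strict_tendency",
           "tendency_inversion", "tendency_table"]


@dataclasses.dataclass
class TendencyCall:
    """Tendency label of one site in one dataset, with the test behind it."""

    site_id: str
    dataset_id: str
    n_lower: int    # values in [0, 0.5)
    n_upper: int    # values in (0.5, 1]
    n_half: int     # values exactly 0.5 (in neither interval)
    chi2: float
    p_value: float
    label: str          # MTS | UTS | NTS
    strict_label: str   # strict_MTS | strict_UTS | none

    @property
    def n(self) -> int:
        return self.n_lower + self.n_upper + self.n_half


def _counts(arr: np.ndarray) -> tuple[int, int, int]:
    lower = int(np.sum(arr < 0.5))
    upper = int(np.sum(arr > 0.5))
    half = int(arr.size - lower - upper)
    return lower, upper, half


def classify_tendency(
    values: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    min_n: int = 4,
    site_id: str = "",
    dataset_id: str = "",
) -> TendencyCall:
    """Classify one site as MTS, UTS or NTS.

    Chi-square goodness of fit of (n_lower, n_upper) against a 50/50 split,
    no continuity correction. ``min_n = 4`` operationalises the requirement
    of sample sizes larger than 3. If every value equals 0.5 exactly the
    site is NTS with p = 1 by convention (logged as a warning).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < min_n:
        raise InsufficientSamplesError(
            f"tendency call needs >= {min_n} values, got {arr.size}"
        )
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidInputError("beta values must lie in [0, 1]")
    lower, upper, half = _counts(arr)
    if lower + upper == 0:
        warnings.warn("all beta values exactly 0.5; NTS by convention", stacklevel=2)
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.chisquare([lower, upper])
        chi2, p = float(chi2), float(p)
    if p <= alpha and upper > lower:
        label = "MTS"
    elif p <= alpha and lower > upper:
        label = "UTS"
    else:
        label = "NTS"
    return TendencyCall(
        site_id=site_id, dataset_id=dataset_id,
        n_lower=lower, n_upper=upper, n_half=half,
        chi2=chi2, p_value=p, label=label,
        strict_label=strict_tendency(arr),
    )


def strict_tendency(values) -> str:
    """``strict_MTS`` iff all values > 0.5, ``strict_UTS`` iff all < 0.5, else ``none``.

    A value of exactly 0.5 satisfies neither strict inequality.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InvalidInputError("strict_tendency of empty input")
    if np.all(arr > 0.5):
        return "strict_MTS"
    if np.all(arr < 0.5):
        return "strict_UTS"
    return "none"


def tendency_inversion(call_a: TendencyCall, call_b: TendencyCall) -> bool:
    """True iff the site flips between MTS and UTS across the two calls."""
    if call_a.site_id != call_b.site_id:
        raise InvalidInputError(
            f"inversion compares one site, got {call_a.site_id!r} vs {call_b.site_id!r}"
        )
    return {call_a.label, call_b.label} == {"MTS", "UTS"}


def tendency_table(
    m: BetaMatrix,
    sample_sheet: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_n: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tendency calls per (site, dataset) plus per-dataset label fractions.

    Datasets come from the sample sheet's DATASET_ID column; without a
    sheet the whole matrix is one dataset. Datasets with fewer than
    ``min_n`` samples are skipped with a warning, as are sites whose
    non-missing count within a dataset falls below ``min_n``.

    Returns ``(calls, summary)``: calls has columns SITE, DATASET, N,
    N_LOWER, N_UPPER, N_HALF, CHI2, P, LABEL, STRICT; summary has one row
    per dataset with the MTS/UTS/NTS fractions.
    """
    if sample_sheet is None:
        groups = {m.dataset_id or "all": list(m.sample_ids)}
    else:
        groups = groups_from_sheet(sample_sheet)
    rows = []
    for dataset, samples in groups.items():
        samples = [s for s in samples if s in m.data.columns]
        if len(samples) < min_n:
            warnings.warn(
                f"dataset {dataset!r} has {len(samples)} samples (< {min_n}); skipped",
                stacklevel=2,
            )
            continue
        sub = m.data[samples]
        for site in m.site_ids:
            vals = sub.loc[site].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < min_n:
                continue
            call = classify_tendency(vals, alpha=alpha, min_n=min_n,
                                     site_id=site, dataset_id=dataset)
            rows.append({
                "SITE": call.site_id, "DATASET": call.dataset_id, "N": call.n,
                "N_LOWER": call.n_lower, "N_UPPER": call.n_upper,
                "N_HALF": call.n_half, "CHI2": call.chi2, "P": call.p_value,
                "LABEL": call.label, "STRICT": call.strict_label,
            })
    calls = pd.DataFrame(rows, columns=["SITE", "DATASET", "N", "N_LOWER", "N_UPPER",
                                        "N_HALF", "CHI2", "P", "LABEL", "STRICT"])
    summaries = []
    for dataset, grp in calls.groupby("DATASET"):
        n = len(grp)
        summaries.append({
            "DATASET": dataset, "N_SITES": n,
            "FRAC_MTS": float((grp["LABEL"] == "MTS").sum() / n),
            "FRAC_UTS": float((grp["LABEL"] == "UTS").sum() / n),
            "FRAC_NTS": float((grp["LABEL"] == "NTS").sum() / n),
        })
    summary = pd.DataFrame(summaries, columns=["DATASET", "N_SITES", "FRAC_MTS",
                                               "FRAC_UTS", "FRAC_NTS"])
    return calls, summary
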