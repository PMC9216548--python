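"""Split methylation: homogeneity testing, k-medoids clustering, stratification.

Split methylation is the presence of multiple aggregated methylation
tendencies at one site within one dataset — two or three peaks in the
r-beta curve, typically driven by probe SNPs (one cluster per genotype at
Hardy-Weinberg proportions) or by sex-linked methylation. Detection runs in
two stages:

1. a Duda-Hart homogeneity test: the ratio of the within-cluster sum of
   squares of the best 2-cluster split to the total sum of squares is
   compared against a normal-approximation critical value; a small ratio
   rejects homogeneity;
2. for heterogeneous sites, k-medoids clustering (the PAM objective,
   solved exactly for 1-D data) is run for k = 2..k_max and the k with the
   largest average silhouette width is selected.

Combining the cluster assignments of several split sites stratifies
samples into composite groups.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .errors import InvalidInputError, InvalidParameterError
from .io import BetaMatrix

__all__ = ["SplitCall", "StratificationResult", "pam_1d", "duda_hart",
           "select_k", "detect_split_sites", "split_table", "stratify"]

_TOL = 1e-12


@dataclasses.dataclass
class SplitCall:
    """Homogeneity verdict and clustering of one site's beta values."""

    site_id: str
    homogeneous: bool
    k: int
    medoids: list[float]            # ascending; length k
    assignments: np.ndarray         # 1-based cluster index per value
    avg_silhouette: float           # NaN for k = 1
    dh_ratio: float
    dh_critical: float


def _segment_costs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """L1 cost and medoid index of every contiguous segment of sorted ``x``.

    The medoid of a segment is its (lower) median element; its cost is the
    total absolute deviation, computed from prefix sums.
    """
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    cost = np.zeros((n, n))
    medoid = np.zeros((n, n), dtype=int)
    for i in range(n):
        j = np.arange(i, n)
        m = (i + j) // 2  # lower median: deterministic, L1-optimal
        left = x[m] * (m - i + 1) - (prefix[m + 1] - prefix[i])
        right = (prefix[j + 1] - prefix[m + 1]) - x[m] * (j - m)
        cost[i, i:] = np.maximum(left + right, 0.0)  # guard prefix-sum round-off
        medoid[i, i:] = m
    return cost, medoid


def pam_1d(values, k: int) -> tuple[list[float], np.ndarray, float]:
    """Exact k-medoids on 1-D data with absolute-difference distance.

    Minimizes the PAM objective (total absolute deviation of each point to
    its cluster medoid, the medoids being data points). In one dimension
    the optimal clusters are contiguous runs of the sorted values, so the
    global optimum is found by dynamic programming over segment boundaries
    — unlike the generic BUILD+SWAP local search, which can stall in
    single-swap local optima. Deterministic: the input is canonicalized by
    a stable sort; cost ties are broken toward the earliest boundary and
    each segment's medoid is its lower median.

    Returns (medoid values ascending, 1-based assignments in the original
    input order with clusters numbered by ascending medoid, total cost).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    distinct = np.unique(arr).size
    if k > distinct:
        raise InvalidParameterError(f"k={k} exceeds the {distinct} distinct values")
    order = np.argsort(arr, kind="stable")
    x = arr[order]
    seg_cost, seg_medoid = _segment_costs(x)

    # dp[c][j] = best cost of splitting x[0..j] into c+1 segments
    dp = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    dp[0] = seg_cost[0]
    for c in range(1, k):
        for j in range(c, n):
            cands = dp[c - 1, c - 1:j] + seg_cost[c:j + 1, j]
            i = int(np.argmin(cands))  # first index on ties
            dp[c, j] = cands[i]
            back[c, j] = i + c  # start of the last segment
    total_cost = float(dp[k - 1, n - 1])

    bounds = []
    j = n - 1
    for c in range(k - 1, -1, -1):
        start = int(back[c, j]) if c > 0 else 0
        bounds.append((start, j))
        j = start - 1
    bounds.reverse()

    medoids = [float(x[seg_medoid[i, j]]) for i, j in bounds]
    labels_sorted = np.empty(n, dtype=int)
    for label, (i, j) in enumerate(bounds, start=1):
        labels_sorted[i:j + 1] = label
    assignments = np.empty(n, dtype=int)
    assignments[order] = labels_sorted
    return medoids, assignments, total_cost


def duda_hart(values, alpha: float = 0.001) -> tuple[bool, float, float]:
    """Duda-Hart test: should these values be split into two clusters?

    The statistic is ``SS_within(best 2-cluster split) / SS(one cluster)``
    with the 2-partition taken from PAM; the critical value, for dimension
    p = 1 and the upper-alpha standard-normal quantile z, is
    ``1 - 2/(pi p) - z sqrt(2 (1 - 8/(pi^2 p)) / (n p))``. Homogeneous iff
    the ratio is at least the critical value. All-identical input is
    homogeneous by convention (SS = 0).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n < 4:
        raise InvalidInputError("Duda-Hart needs at least 4 values")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    z = float(stats.norm.ppf(1 - alpha))
    p = 1.0
    critical = 1 - 2 / (np.pi * p) - z * np.sqrt(
        2 * (1 - 8 / (np.pi**2 * p)) / (n * p)
    )
    ss1 = float(np.sum((arr - arr.mean()) ** 2))
    if ss1 == 0.0:
        warnings.warn("all values identical; homogeneous by convention", stacklevel=2)
        return True, 1.0, float(critical)
    _, assignments, _ = pam_1d(arr, 2)
    ssw = 0.0
    for c in (1, 2):
        grp = arr[assignments == c]
        ssw += float(np.sum((grp - grp.mean()) ** 2))
    ratio = ssw / ss1
    return bool(ratio >= critical), float(ratio), float(critical)


def select_k(values, k_max: int = 10, alpha: float = 0.001, site_id: str = "") -> SplitCall:
    """Cluster-number selection: Duda-Hart gate, then best-silhouette PAM.

    Homogeneous input yields k = 1 (the medoid is a median element). For
    heterogeneous input, PAM runs for k in 2..min(k_max, distinct - 1)
    (never fewer than 2 candidates' worth: two distinct values force
    k = 2) and the k with the largest average silhouette width wins;
    ties go to the smaller k.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 4:
        raise InvalidInputError("cluster-number selection needs at least 4 values")
    homogeneous, ratio, critical = duda_hart(arr, alpha=alpha)
    if homogeneous:
        medoids, assignments, _ = pam_1d(arr, 1)
        return SplitCall(site_id, True, 1, medoids, assignments,
                         float("nan"), ratio, critical)
    distinct = np.unique(arr).size
    upper = max(2, min(k_max, distinct - 1, arr.size - 1))
    best = None
    for k in range(2, upper + 1):
        medoids, assignments, _ = pam_1d(arr, k)
        sil = float(silhouette_score(arr.reshape(-1, 1), assignments))
        if best is None or sil > best[0] + _TOL:
            best = (sil, k, medoids, assignments)
    sil, k, medoids, assignments = best
    return SplitCall(site_id, False, k, medoids, assignments, sil, ratio, critical)


def detect_split_sites(
    m: BetaMatrix, k_max: int = 10, alpha: float = 0.001
) -> dict[str, SplitCall]:
    """One SplitCall per site; split sites are those with k >= 2.

    Sites with fewer than 4 non-missing values are skipped with a warning.
    """
    calls: dict[str, SplitCall] = {}
    for site in m.site_ids:
        vals = m.site_values(site)
        if vals.size < 4:
            warnings.warn(f"site {site!r} has {vals.size} values (< 4); skipped",
                          stacklevel=2)
            continue
        calls[site] = select_k(vals, k_max=k_max, alpha=alpha, site_id=site)
    return calls


def split_table(calls: Mapping[str, SplitCall]) -> pd.DataFrame:
    """Tabular view of split calls (medoids joined by ';')."""
    rows = [{
        "SITE": c.site_id,
        "HOMOGENEOUS": c.homogeneous,
        "K": c.k,
        "MEDOIDS": ";".join(f"{v:.6g}" for v in c.medoids),
        "SILHOUETTE": c.avg_silhouette,
        "DH_RATIO": c.dh_ratio,
        "DH_CRITICAL": c.dh_critical,
    } for c in calls.values()]
    return pd.DataFrame(rows, columns=["SITE", "HOMOGENEOUS", "K", "MEDOIDS",
                                       "SILHOUETTE", "DH_RATIO", "DH_CRITICAL"])


@dataclasses.dataclass
class StratificationResult:
    """Composite sample grouping from the cluster assignments of split sites."""

    sites_used: list[str]
    labels: dict[str, tuple[int, ...]]     # sample -> per-site cluster indices
    groups: list[tuple[tuple[int, ...], list[str]]]  # descending size
    sample_order: list[str]                # heatmap-friendly ordering

    @property
    def group_count(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        group_rank = {label: i + 1 for i, (label, _) in enumerate(self.groups)}
        for sample, label in self.labels.items():
            row = {"SAMPLE": sample, "GROUP": group_rank[label]}
            row.update({f"CLUSTER_{s}": c for s, c in zip(self.sites_used, label)})
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.set_index("SAMPLE").loc[self.sample_order].reset_index()


def stratify(
    m: BetaMatrix,
    sites: Sequence[str],
    calls: Mapping[str, SplitCall] | None = None,
    k_max: int = 10,
    alpha: float = 0.001,
) -> StratificationResult:
    """Stratify samples by the combined cluster assignments of split sites.

    Each sample's label is the tuple of its per-site cluster indices, so at
    most the product of the per-site k values distinct groups can occur;
    correlated sites yield fewer. Groups are ordered by descending size
    (ties by label) and the emitted sample ordering sorts samples by group
    then ID, suitable for heatmap rendering with the sites in given order.

    Every listed site must have a split call with k >= 2; samples missing a
    value at any listed site are excluded with a warning.
    """
    if not sites:
        raise InvalidInputError("stratify needs at least one site")
    for site in sites:
        if site not in m.data.index:
            raise InvalidInputError(f"site {site!r} not in matrix")
    site_assign: dict[str, dict[str, int]] = {}
    for site in sites:
        row = m.data.loc[site]
        present = row.dropna()
        if calls is not None and site in calls:
            call = calls[site]
            if call.assignments.size != present.size:
                # recompute against this matrix to keep sample alignment
                call = select_k(present.to_numpy(), k_max=k_max, alpha=alpha, site_id=site)
        else:
            call = select_k(present.to_numpy(), k_max=k_max, alpha=alpha, site_id=site)
        if call.k < 2:
            raise InvalidInputError(f"site {site!r} is homogeneous (k=1); not a split site")
        site_assign[site] = dict(zip(present.index, call.assignments.tolist()))

    labels: dict[str, tuple[int, ...]] = {}
    excluded = []
    for sample in m.sample_ids:
        try:
            labels[sample] = tuple(site_assign[s][sample] for s in sites)
        except KeyError:
            excluded.append(sample)
    if excluded:
        warnings.warn(f"{len(excluded)} sample(s) missing a value at a split site; excluded",
                      stacklevel=2)
    by_label: dict[tuple[int, ...], list[str]] = {}
    for sample, label in labels.items():
        by_label.setdefault(label, []).append(sample)
    groups = sorted(by_label.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    sample_order = [s for _, members in groups for s in sorted(members)]
    return StratificationResult(list(sites), labels, groups, sample_order)
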