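"""Methylation profiles: r-beta curves and kernel-density summaries.

The r-beta curve of a site is built by rounding each sample's beta value to
two decimals — placing it on the 101-point grid 0.00, 0.01, ..., 1.00 — and
plotting the proportion of samples at each grid point. The proportions of a
complete (no-missing) profile sum to exactly 1. Curve shape conveys both
methylation intensity (peak position) and plasticity (width, multiple
peaks).
"""

from __future__ import annotations

import dataclasses
import json
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["GRID", "MethylationProfile", "round_to_grid", "rbeta_profile",
           "profile_peaks", "kde_density", "mirror_profile"]

#: The 101 rounded beta values 0.00 .. 1.00.
GRID: np.ndarray = np.round(np.arange(101) / 100.0, 2)
GRID.setflags(write=False)


def round_to_grid(values: np.ndarray) -> np.ndarray:
    """Grid bin index (0..100) of each value: round-half-to-even at 2 decimals.

    Round-half-even matches the banker's rounding of R's ``round``; the rule
    is centralized here so a half-up alternative is a one-line change.
    """
    return np.round(np.asarray(values, dtype=float) * 100.0).astype(int)


@dataclasses.dataclass
class MethylationProfile:
    """Per-site sample-proportion vector over the 101-point rounded-beta grid.

    ``counts[b]`` is the number of samples whose rounded beta value equals
    ``GRID[b]``; ``proportions`` divides by ``n_samples`` (the count of
    non-missing values), so a complete profile integrates to 1.
    """

    site_id: str
    dataset_id: str
    counts: np.ndarray  # length 101, ints
    n_samples: int

    @property
    def grid(self) -> np.ndarray:
        return GRID

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_samples

    def exact_proportions(self) -> list[Fraction]:
        """Proportions as exact rationals count/n."""
        return [Fraction(int(c), self.n_samples) for c in self.counts]

    def to_json(self) -> str:
        return json.dumps({
            "site": self.site_id,
            "dataset": self.dataset_id,
            "n": self.n_samples,
            "proportions": [float(p) for p in self.proportions],
        })

    @classmethod
    def from_json(cls, text: str) -> "MethylationProfile":
        obj = json.loads(text)
        props = np.asarray(obj["proportions"], dtype=float)
        counts = np.round(props * obj["n"]).astype(int)
        return cls(obj["site"], obj["dataset"], counts, obj["n"])

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: SITE, GRID, PROPORTION."""
        with open(path, "w") as fh:
            fh.write("SITE\tGRID\tPROPORTION\n")
            for g, p in zip(GRID, self.proportions):
                fh.write(f"{self.site_id}\t{g:.2f}\t{p:.10g}\n")


def rbeta_profile(
    values: Sequence[float] | np.ndarray,
    site_id: str = "",
    dataset_id: str = "",
) -> MethylationProfile:
    """Build the r-beta profile of one site from its beta values.

    Missing values (NaN) are excluded before binning; ``n_samples`` records
    the post-exclusion count. Raises on empty or out-of-range input.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InvalidInputError("no non-missing beta values to profile")
    if arr.min() < 0 or arr.max() > 1:
        raise InvalidInputError("beta values must lie in [0, 1]")
    bins = round_to_grid(arr)
    counts = np.bincount(bins, minlength=101)
    return MethylationProfile(site_id, dataset_id, counts, int(arr.size))


def mirror_profile(p: MethylationProfile) -> MethylationProfile:
    """Profile of the mirrored data v -> 1 - v: the proportion vector reversed."""
    return MethylationProfile(p.site_id, p.dataset_id, p.counts[::-1].copy(), p.n_samples)


def profile_peaks(
    p: MethylationProfile,
    min_prominence: float = 0.02,
    smooth_window: int = 5,
) -> list[tuple[float, float]]:
    """Peaks of the smoothed r-beta curve, as (grid point, height) pairs.

    The proportion vector is smoothed with a centred moving average of
    ``smooth_window`` bins (odd), then local maxima with prominence at least
    ``min_prominence`` are reported, sorted by grid point. Zero padding at
    both ends lets boundary peaks (fully un/methylated sites) be detected.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise InvalidParameterError("smooth_window must be a positive odd integer")
    props = p.proportions
    kernel = np.ones(smooth_window) / smooth_window
    # pad one bin beyond the kernel radius so plateaus at 0.00/1.00 have an
    # interior neighbour and boundary peaks are still found
    pad = smooth_window // 2 + 1
    padded = np.concatenate([np.zeros(pad), props, np.zeros(pad)])
    smoothed = np.convolve(padded, kernel, mode="same")
    idx, _ = signal.find_peaks(smoothed, prominence=min_prominence)
    idx = idx - pad
    idx = idx[(idx >= 0) & (idx <= 100)]
    return [(float(GRID[i]), float(smoothed[i + pad])) for i in sorted(idx)]


def kde_density(
    values: Sequence[float] | np.ndarray,
    bandwidth: float | None = None,
    n_points: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of beta values on [-0.05, 1.05].

    Bandwidth defaults to Silverman's rule of thumb
    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``; degenerate (constant) input
    falls back to a narrow fixed bandwidth so the single mode stays visible.
    Returns (grid of ``n_points`` points, density values).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise InvalidInputError("kernel density needs at least 2 values")
    if bandwidth is None:
        sd = float(np.std(arr, ddof=1))
        iqr = float(np.subtract(*np.percentile(arr, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * arr.size ** (-0.2)
        if bandwidth <= 1e-9:  # (near-)constant input: keep the mode visible
            bandwidth = 0.01
    elif bandwidth <= 0:
        raise InvalidParameterError("bandwidth must be positive")
    grid = np.linspace(-0.05, 1.05, n_points)
    sd = float(np.std(arr))
    if sd > 1e-9:
        kde = stats.gaussian_kde(arr, bw_method=bandwidth / sd)
        density = kde(grid)
    else:
        # all values identical: evaluate the Gaussian kernel directly
        density = np.exp(-0.5 * ((grid - arr[0]) / bandwidth) ** 2)
        density /= bandwidth * np.sqrt(2 * np.pi)
    return grid, density
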