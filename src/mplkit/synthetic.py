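"""Synthetic methylome generation with truth labels.

Emulates the statistical structure the analysis framework assumes so every
module can be exercised offline: genome-wide bimodal beta values, tendency
structure (most sites clearly methylated or unmethylated, a few balanced),
genotype-driven trimodal split sites at Hardy-Weinberg proportions, and
sex-linked bimodal sites. Each site draws per-sample component memberships
and then a beta value from a Beta distribution parameterized by the
component mean and a concentration kappa — shapes (mean*kappa,
(1-mean)*kappa) — so per-component noise looks like array data
(sd ~ 0.05-0.07 at kappa 50).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import BetaMatrix

__all__ = ["SiteSpec", "TruthTable", "CorpusBundle", "generate", "preset_corpus"]

KINDS = ("MTS_like", "UTS_like", "NTS_like", "split_hwe", "split_sex")

#: Guard band keeping draws strictly inside (0, 1) so no bin degenerates.
_EPS = 1e-6


@dataclasses.dataclass
class SiteSpec:
    """Generative recipe for one site.

    ``component_means`` lists the 1-3 cluster centres (ascending);
    ``component_concentration`` is the Beta-distribution precision kappa.
    ``split_hwe`` sites draw a genotype per sample at Hardy-Weinberg
    proportions (p^2, 2pq, q^2 from ``allele_freq`` q = alternate-allele
    frequency) with one mean per genotype; ``split_sex`` sites use
    ``sex_effect = (female mean, male mean)``. ``condition_shift`` moves
    every component mean for samples in the "case" condition — the handle
    for engineering differential sites.
    """

    site_id: str
    kind: str
    component_means: tuple[float, ...]
    component_concentration: float = 50.0
    allele_freq: float | None = None
    sex_effect: tuple[float, float] | None = None
    condition_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown site kind {self.kind!r}")
        means = tuple(float(v) for v in self.component_means)
        if not means or len(means) > 3:
            raise InvalidParameterError("component_means needs 1-3 entries")
        if any(not 0 <= v <= 1 for v in means):
            raise InvalidParameterError("component means must lie in [0, 1]")
        if list(means) != sorted(means):
            raise InvalidParameterError("component_means must be sorted ascending")
        if self.component_concentration <= 0:
            raise InvalidParameterError("component_concentration must be positive")
        if self.kind == "split_hwe":
            if len(means) != 3:
                raise InvalidParameterError("split_hwe needs exactly 3 component means")
            if self.allele_freq is None or not 0 < self.allele_freq < 1:
                raise InvalidParameterError("split_hwe needs allele_freq in (0, 1)")
        if self.kind == "split_sex":
            if self.sex_effect is None or len(self.sex_effect) != 2:
                raise InvalidParameterError("split_sex needs sex_effect = (F mean, M mean)")
        if self.condition_shift and self.kind in ("split_hwe", "split_sex"):
            raise InvalidParameterError("condition_shift applies to single-component kinds only")
        self.component_means = means

    @property
    def true_k(self) -> int:
        if self.kind == "split_hwe":
            return 3
        if self.kind == "split_sex":
            return 2
        return 1

    @property
    def true_tendency(self) -> str | None:
        """Expected tendency label for single-component kinds, else None."""
        return {"MTS_like": "MTS", "UTS_like": "UTS", "NTS_like": "NTS"}.get(self.kind)


@dataclasses.dataclass
class TruthTable:
    """Ground truth accompanying a generated matrix.

    ``sites`` has one row per site (SITE, KIND, TRUE_K, TRUE_TENDENCY,
    IS_DIFFERENTIAL); ``components`` is a sites x samples frame of
    0-based component indices (genotype index for HWE sites, 0 = F / 1 = M
    for sex sites, 0 otherwise).
    """

    sites: pd.DataFrame
    components: pd.DataFrame


@dataclasses.dataclass
class CorpusBundle:
    matrix: BetaMatrix
    sample_sheet: pd.DataFrame
    truth: TruthTable


def _draw_beta(rng: np.random.Generator, mean: np.ndarray, kappa: float) -> np.ndarray:
    mean = np.clip(mean, _EPS, 1 - _EPS)
    draws = rng.beta(mean * kappa, (1 - mean) * kappa)
    return np.clip(draws, _EPS, 1 - _EPS)


def generate(
    specs: Sequence[SiteSpec],
    n_samples: int,
    seed: int,
    sex_ratio: float = 0.5,
    conditions: Sequence[str] | None = None,
    dataset_id: str = "synthetic",
) -> CorpusBundle:
    """Generate a beta matrix, sample sheet and truth table from site specs.

    Sex is Bernoulli(``sex_ratio``) per sample (probability of male) and
    recorded in the sheet. ``conditions`` optionally labels each sample
    ("control"/"case"); case samples receive each spec's
    ``condition_shift``. Identical (specs, n_samples, seed) give identical
    output.
    """
    if n_samples < 4:
        raise InvalidParameterError("n_samples must be >= 4")
    if conditions is not None and len(conditions) != n_samples:
        raise InvalidParameterError("conditions must have one entry per sample")
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    is_male = rng.random(n_samples) < sex_ratio
    sexes = np.where(is_male, "M", "F")
    cond = np.asarray(conditions if conditions is not None else ["control"] * n_samples)
    is_case = cond == "case"

    values = np.empty((len(specs), n_samples))
    comp_rows = np.zeros((len(specs), n_samples), dtype=int)
    site_rows = []
    for i, spec in enumerate(specs):
        kappa = spec.component_concentration
        if spec.kind == "split_hwe":
            q = spec.allele_freq
            probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
            comp = rng.choice(3, size=n_samples, p=probs)
            means = np.asarray(spec.component_means)[comp]
        elif spec.kind == "split_sex":
            comp = is_male.astype(int)
            means = np.where(is_male, spec.sex_effect[1], spec.sex_effect[0])
        else:
            comp = np.zeros(n_samples, dtype=int)
            means = np.full(n_samples, spec.component_means[0])
        true_k = spec.true_k
        if spec.condition_shift:
            means = means + np.where(is_case, spec.condition_shift, 0.0)
            if is_case.any() and not is_case.all():
                # pooled across conditions the site is a genuine 2-component mixture
                comp = is_case.astype(int)
                true_k = 2
        values[i] = _draw_beta(rng, means, kappa)
        comp_rows[i] = comp
        site_rows.append({
            "SITE": spec.site_id, "KIND": spec.kind, "TRUE_K": true_k,
            "TRUE_TENDENCY": spec.true_tendency or "",
            "IS_DIFFERENTIAL": bool(spec.condition_shift),
        })

    site_ids = [s.site_id for s in specs]
    matrix = BetaMatrix(pd.DataFrame(values, index=site_ids, columns=sample_ids),
                        dataset_id=dataset_id)
    sheet = pd.DataFrame({
        "SAMPLE_ID": sample_ids,
        "DATASET_ID": dataset_id,
        "TISSUE": "peripheral_blood",
        "CELL_TYPE": "whole_blood",
        "CONDITION": cond,
        "SEX": sexes,
        "AGE": np.round(rng.uniform(20, 70, n_samples), 1),
    })
    truth = TruthTable(
        sites=pd.DataFrame(site_rows),
        components=pd.DataFrame(comp_rows, index=site_ids, columns=sample_ids),
    )
    return CorpusBundle(matrix, sheet, truth)


def preset_corpus(seed: int) -> CorpusBundle:
    """Fixed benchmark bundle exercising the full pipeline.

    1000 sites x 200 samples: 60% methylation-tendency-like, 35%
    unmethylation-tendency-like, 3% nonbiased, 1.5% Hardy-Weinberg
    trimodal split sites (allele frequency 0.5, component means
    0.04/0.45/0.89 — the canonical TT/CT/CC genotype peaks) and 0.5%
    sex-linked bimodal sites (female/male means 0.54/0.82, the X-linked
    pattern). Samples split 100/100 into control and case conditions, with
    50 of the unmethylated-tendency sites given a +0.3 case mean shift as
    engineered differential sites. Unimodal components use kappa = 50;
    split components use kappa = 100 so each genotype/sex cluster forms
    the distinct, narrow peak this structure produces in real profiles.
    """
    rng = np.random.default_rng(seed)
    n_sites, n_samples = 1000, 200
    n_mts, n_uts, n_nts, n_hwe, n_sex = 600, 350, 30, 15, 5
    n_diff = 50

    specs: list[SiteSpec] = []
    idx = 0

    def sid() -> str:
        nonlocal idx
        idx += 1
        return f"cg{idx:08d}"

    for _ in range(n_mts):
        specs.append(SiteSpec(sid(), "MTS_like",
                              (float(rng.uniform(0.70, 0.95)),)))
    diff_flags = [True] * n_diff + [False] * (n_uts - n_diff)
    for is_diff in diff_flags:
        mean = float(rng.uniform(0.10, 0.20)) if is_diff else float(rng.uniform(0.05, 0.30))
        specs.append(SiteSpec(sid(), "UTS_like", (mean,),
                              condition_shift=0.3 if is_diff else 0.0))
    for _ in range(n_nts):
        # balanced probe signal: mean exactly 0.5, so neither interval is favoured
        specs.append(SiteSpec(sid(), "NTS_like", (0.5,)))
    for _ in range(n_hwe):
        specs.append(SiteSpec(sid(), "split_hwe", (0.04, 0.45, 0.89),
                              component_concentration=100.0, allele_freq=0.5))
    for _ in range(n_sex):
        specs.append(SiteSpec(sid(), "split_sex", (0.54, 0.82),
                              component_concentration=100.0,
                              sex_effect=(0.54, 0.82)))
    assert len(specs) == n_sites

    conditions = ["control"] * (n_samples // 2) + ["case"] * (n_samples // 2)
    # derive the generation seed from the bundle seed, kept below 2**31
    gen_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    return generate(specs, n_samples, seed=gen_seed, conditions=conditions,
                    dataset_id="preset_corpus")
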