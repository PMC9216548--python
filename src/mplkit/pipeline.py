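"""End-to-end analysis pipeline: QC -> profiles -> plasticity -> tendency ->
split detection -> differential methylation -> stratification.

Configuration mirrors the CLI flags and can be loaded from YAML; CLI values
override the file. Every stage writes its table into the run directory and
a JSON manifest records each output with its row count. Stages never mutate
their inputs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import io as mio
from . import plasticity as mpl
from .diffmeth import differential_table
from .errors import InvalidParameterError, MplkitError
from .profiles import rbeta_profile
from .split import detect_split_sites, split_table, stratify
from .tendency import tendency_table

__all__ = ["RunConfig", "run_pipeline", "EXIT_OK", "EXIT_USAGE", "EXIT_DATA", "EXIT_INTERNAL"]

EXIT_OK, EXIT_USAGE, EXIT_DATA, EXIT_INTERNAL = 0, 1, 2, 3

log = logging.getLogger("mplkit")


@dataclasses.dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    matrix: str
    out_dir: str
    samples: str | None = None
    group_a: str | None = None
    group_b: str | None = None
    alpha_tendency: float = 0.05
    alpha_duda_hart: float = 0.001
    alpha_diff: float = 0.05
    mpl_method: str = "iqr"
    mpl_threshold: float = 0.5
    k_max: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("alpha_tendency", "alpha_duda_hart", "alpha_diff"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise InvalidParameterError(f"{name} must lie in (0, 1], got {a}")
        if self.mpl_method not in mpl.MPL_METHODS:
            raise InvalidParameterError(f"unknown MPL method {self.mpl_method!r}")
        if not 0 <= self.mpl_threshold <= 1:
            raise InvalidParameterError("mpl_threshold must lie in [0, 1]")
        if self.k_max < 2:
            raise InvalidParameterError("k_max must be >= 2")
        if not Path(self.matrix).exists():
            raise InvalidParameterError(f"matrix file not found: {self.matrix}")
        if self.samples is not None and not Path(self.samples).exists():
            raise InvalidParameterError(f"sample sheet not found: {self.samples}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _write(df, path: Path) -> dict:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return {"path": path.name, "rows": int(len(df))}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest. Raises on any stage failure."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": []}

    def stage(name: str):
        log.info("stage %s starting", name)
        return time.monotonic()

    def done(name: str, t0: float, n_in: int, n_out: int) -> None:
        log.info("stage %s done: %d sites in, %d rows out, %.2fs",
                 name, n_in, n_out, time.monotonic() - t0)

    t0 = stage("qc")
    matrix = mio.read_beta_matrix(config.matrix)
    sheet = (mio.read_sample_sheet(config.samples, matrix)
             if config.samples else None)
    clean, report = mio.qc_filter_samples(matrix)
    qc_path = out / "qc_report.json"
    qc_path.write_text(json.dumps(report.dropped, indent=1))
    manifest["outputs"].append({"path": qc_path.name, "rows": report.n_dropped})
    done("qc", t0, matrix.n_samples, clean.n_samples)

    t0 = stage("profiles")
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("SITE\tGRID\tPROPORTION\n")
        n_rows = 0
        for site in clean.site_ids:
            prof = rbeta_profile(clean.site_values(site), site_id=site,
                                 dataset_id=clean.dataset_id or "all")
            for g, p in zip(prof.grid, prof.proportions):
                if p > 0:
                    fh.write(f"{site}\t{g:.2f}\t{p:.10g}\n")
                    n_rows += 1
    manifest["outputs"].append({"path": "profiles.tsv", "rows": n_rows})
    done("profiles", t0, clean.n_sites, n_rows)

    t0 = stage("plasticity")
    scores = mpl.plasticity_table(clean, method=config.mpl_method)
    manifest["outputs"].append(_write(scores, out / "plasticity.tsv"))
    high = scores[scores["SCORE"] >= config.mpl_threshold]
    done("plasticity", t0, clean.n_sites, len(scores))

    t0 = stage("tendency")
    calls, summary = tendency_table(clean, sheet, alpha=config.alpha_tendency)
    manifest["outputs"].append(_write(calls, out / "tendency.tsv"))
    manifest["outputs"].append(_write(summary, out / "tendency_summary.tsv"))
    done("tendency", t0, clean.n_sites, len(calls))

    t0 = stage("split")
    split_calls = detect_split_sites(clean, k_max=config.k_max,
                                     alpha=config.alpha_duda_hart)
    stable = split_table(split_calls)
    manifest["outputs"].append(_write(stable, out / "split.tsv"))
    split_sites = [s for s, c in split_calls.items() if c.k >= 2]
    done("split", t0, clean.n_sites, len(stable))

    if config.group_a and config.group_b:
        if sheet is None:
            raise InvalidParameterError("differential analysis needs a sample sheet")
        t0 = stage("diff")
        cols = {"DATASET_ID": "DATASET_ID", "CONDITION": "CONDITION"}
        by_cond = {}
        for _, row in sheet.iterrows():
            if row["SAMPLE_ID"] not in clean.data.columns:
                continue
            for col in cols:
                by_cond.setdefault(row[col], []).append(row["SAMPLE_ID"])
        for grp in (config.group_a, config.group_b):
            if grp not in by_cond:
                raise InvalidParameterError(f"group {grp!r} not found in sample sheet")
        diff = differential_table(clean, by_cond[config.group_a],
                                  by_cond[config.group_b], alpha=config.alpha_diff)
        manifest["outputs"].append(_write(diff, out / "diff.tsv"))
        done("diff", t0, clean.n_sites, len(diff))

    if split_sites:
        t0 = stage("stratify")
        strat = stratify(clean, split_sites, calls=split_calls)
        manifest["outputs"].append(_write(strat.to_frame(), out / "stratification.tsv"))
        groups_json = out / "stratification_groups.json"
        groups_json.write_text(json.dumps({
            "sites_used": strat.sites_used,
            "group_count": strat.group_count,
            "groups": [{"label": list(lbl), "n": len(members)}
                       for lbl, members in strat.groups],
        }, indent=1))
        manifest["outputs"].append({"path": groups_json.name, "rows": strat.group_count})
        done("stratify", t0, len(split_sites), strat.group_count)

    manifest["n_high_plasticity_sites"] = int(len(high))
    manifest["n_split_sites"] = len(split_sites)
    for entry in manifest["outputs"]:
        entry["sha256"] = _sha256(out / entry["path"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
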