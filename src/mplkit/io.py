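"""Reading, writing and quality control of beta-value matrices.

A beta value is the fraction of methylated probe signal at a cytosine site,
``beta = Meth / (Meth + Unmeth + offset)``; it ranges from 0 (unmethylated)
to 1 (fully methylated). Matrices are stored sites-in-rows / samples-in-
columns, the GEO series-matrix convention. Missing values are written as
``NA`` on disk and held as ``NaN`` in memory, distinct from 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError, InvalidParameterError

__all__ = [
    "BetaMatrix",
    "QCReport",
    "REGION_CLASSES",
    "CGI_CLASSES",
    "compute_beta",
    "read_beta_matrix",
    "write_beta_matrix",
    "qc_filter_samples",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Gene-region vocabulary of the Illumina manifest (UCSC refgene group).
REGION_CLASSES = frozenset(
    {"1stExon", "3'UTR", "5'UTR", "Body", "TSS200", "TSS1500", "none"}
)

#: Relation of a probe to the nearest CpG island. Shores are 0-2 kb from an
#: island, shelves 2-4 kb; N = upstream (5'), S = downstream (3').
CGI_CLASSES = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)

ANNOTATION_COLUMNS = ["ID", "CHR", "MAPINFO", "GENE", "REGION", "RELATION_TO_CGI", "HAS_SNP"]
SAMPLE_SHEET_COLUMNS = ["SAMPLE_ID", "DATASET_ID", "TISSUE", "CELL_TYPE", "CONDITION", "SEX", "AGE"]


@dataclasses.dataclass
class BetaMatrix:
    """Sites x samples grid of beta values with missing-value support.

    ``data`` is a float DataFrame indexed by site ID with one column per
    sample; ``NaN`` marks a missing beta value. Values outside [0, 1] are
    retained at read time (so the QC filter can report them) but every
    analysis routine assumes the matrix has been through
    :func:`qc_filter_samples`.
    """

    data: pd.DataFrame
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate site IDs: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate sample IDs: {dupes[:5]}")
        self.data = self.data.astype(float)

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def site_values(self, site_id: str, dropna: bool = True) -> np.ndarray:
        """Beta values of one site across samples, missing excluded by default."""
        row = self.data.loc[site_id]
        arr = row.to_numpy(dtype=float)
        return arr[~np.isnan(arr)] if dropna else arr

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise InvalidInputError(f"unknown sample IDs: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)].copy(), dataset_id=self.dataset_id)


@dataclasses.dataclass
class QCReport:
    """Outcome of the per-sample quality filter."""

    dropped: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Beta value from methylated/unmethylated intensities.

    ``beta = meth / (meth + unmeth + offset)``. The offset (default 100)
    stabilises the ratio against near-zero total intensity. Accepts scalars
    or arrays; broadcasting follows numpy rules.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if offset < 0:
        raise InvalidParameterError(f"offset must be >= 0, got {offset}")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise InvalidInputError("intensities must be non-negative")
    denom = meth + unmeth + offset
    if np.any(denom == 0):
        raise InvalidInputError("meth + unmeth + offset must be positive")
    out = meth / denom
    return float(out) if out.ndim == 0 else out


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_beta_matrix(
    path: str | Path,
    dataset_id: str | None = None,
    transpose: bool = False,
) -> BetaMatrix:
    """Read a beta matrix from TSV/CSV (delimiter sniffed on the header line).

    First column holds site IDs, header row sample IDs. Empty cells and
    ``NA``/``NaN`` become missing. Ragged rows, duplicate IDs and
    unparsable numbers raise :class:`FormatError` with a line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError("empty file", line=1)
    sep = _sniff_delimiter(header)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, dtype=str,
            keep_default_na=False, skip_blank_lines=False,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(str(exc)) from exc

    n_fields = len(header.rstrip("\n").split(sep))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            if len(line.rstrip("\n").split(sep)) != n_fields:
                raise FormatError("ragged row", line=lineno)

    if df.index.has_duplicates:
        first_dup = df.index[df.index.duplicated()][0]
        lineno = 2 + int(np.flatnonzero(df.index == first_dup)[1])
        raise FormatError(f"duplicate site ID {first_dup!r}", line=lineno)
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample IDs in header", line=1)

    numeric = df.replace({"NA": np.nan, "NaN": np.nan, "nan": np.nan, "": np.nan})
    try:
        numeric = numeric.astype(float)
    except ValueError:
        for i, (_, row) in enumerate(numeric.iterrows()):
            for cell in row:
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise FormatError(f"unparsable value {cell!r}", line=i + 2)
        raise  # pragma: no cover - unreachable
    if transpose:
        numeric = numeric.T
    return BetaMatrix(numeric, dataset_id=dataset_id)


def write_beta_matrix(m: BetaMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a matrix; delimiter from the file extension unless given (.csv -> comma)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = m.data.copy()
    df.index.name = df.index.name or "ID"
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def qc_filter_samples(m: BetaMatrix) -> tuple[BetaMatrix, QCReport]:
    """Drop samples carrying any abnormal beta value.

    A sample is removed when any of its values is below 0, above 1 or
    missing; sites are never removed and site order is unchanged. The
    operation is idempotent.
    """
    report = QCReport()
    vals = m.data
    keep: list[str] = []
    for sample in m.sample_ids:
        col = vals[sample]
        reasons = []
        if (col < 0).any():
            reasons.append("value < 0")
        if (col > 1).any():
            reasons.append("value > 1")
        if col.isna().any():
            reasons.append("missing value")
        if reasons:
            report.dropped[sample] = reasons
        else:
            keep.append(sample)
    return BetaMatrix(m.data[keep].copy(), dataset_id=m.dataset_id), report


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe annotation (ID, CHR, MAPINFO, GENE, REGION, RELATION_TO_CGI, HAS_SNP).

    Coordinates are 1-based (Illumina MAPINFO). Region and CGI classes are
    validated against the closed manifest vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "CHR": str, "GENE": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation missing columns {missing}")
    if df["ID"].duplicated().any():
        raise FormatError("duplicate probe IDs in annotation")
    bad = set(df["REGION"]) - REGION_CLASSES
    if bad:
        raise FormatError(f"unknown region class(es): {sorted(bad)}")
    bad = set(df["RELATION_TO_CGI"]) - CGI_CLASSES
    if bad:
        raise FormatError(f"unknown CGI class(es): {sorted(bad)}")
    if (df["MAPINFO"] < 0).any():
        raise FormatError("negative MAPINFO coordinate")
    df["HAS_SNP"] = df["HAS_SNP"].astype(bool)
    return df


def write_probe_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def read_sample_sheet(path: str | Path, matrix: BetaMatrix | None = None) -> pd.DataFrame:
    """Read a sample sheet; optionally check every sample exists in ``matrix``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    if df["SAMPLE_ID"].duplicated().any():
        raise FormatError("duplicate sample IDs in sample sheet")
    bad = set(df["SEX"]) - {"F", "M", "unknown"}
    if bad:
        raise FormatError(f"invalid SEX value(s): {sorted(bad)}")
    df["AGE"] = pd.to_numeric(df["AGE"].replace({"": np.nan, "NA": np.nan}))
    if (df["AGE"] < 0).any():
        raise FormatError("negative AGE")
    if matrix is not None:
        unknown = set(df["SAMPLE_ID"]) - set(matrix.sample_ids)
        if unknown:
            raise InvalidInputError(f"sample sheet rows not in matrix: {sorted(unknown)[:5]}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False, na_rep="NA", columns=SAMPLE_SHEET_COLUMNS)


def groups_from_sheet(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """Map dataset ID -> sample IDs, preserving sheet order."""
    out: dict[str, list[str]] = {}
    for _, row in sheet.iterrows():
        out.setdefault(row["DATASET_ID"], []).append(row["SAMPLE_ID"])
    return out
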