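"""Domain containers and delimited-text readers/writers.

The pipeline works on three kinds of tabular inputs, all tab-separated
UTF-8 with a mandatory header row and ``.`` decimal separator:

* gene-by-sample expression matrices (first column gene ids, remaining
  columns one per sample),
* sample designs (one row per sample with age, zeitgeber time, replicate),
* per-study fold-change tables used for the meta-analysis assessment.

Missing values are not permitted in expression matrices: a gene that was
not measured in an assay is simply absent from that matrix.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleDesign",
    "CandidateSet",
    "StudyFoldChangeTable",
    "read_expression_matrix",
    "read_sample_design",
    "read_candidate_list",
    "read_study_fold_changes",
    "write_report",
]

DESIGN_COLUMNS = ("sample_id", "age_months", "zeitgeber_time_h", "replicate")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene-by-sample expression values.

    ``data`` has gene ids as the index and sample ids as the columns.
    Values may be raw counts or normalised abundances; they must be
    finite and non-negative, and both id axes must be duplicate-free.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.name != "gene_id":
            object.__setattr__(self, "data", self.data.rename_axis("gene_id"))
        df = self.data
        _check_unique(df.index.astype(str), "gene id")
        _check_unique(df.columns.astype(str), "sample id")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for the error message
            for g in df.index:
                for s in df.columns:
                    try:
                        float(df.at[g, s])
                    except (TypeError, ValueError):
                        raise FormatError(
                            f"non-numeric value {df.at[g, s]!r} at gene {g!r}, sample {s!r}"
                        ) from None
            raise FormatError("non-numeric expression matrix")
        if values.size:
            bad = ~np.isfinite(values.astype(float)) | (values.astype(float) < 0)
            if bad.any():
                gi, si = np.argwhere(bad)[0]
                raise FormatError(
                    f"negative or non-finite value {values[gi, si]!r} at "
                    f"gene {df.index[gi]!r}, sample {df.columns[si]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def select_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes])

    def select_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[samples])

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        df = self.data.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep=delimiter)


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a gene-by-sample matrix from delimited text.

    The first column holds gene ids, the header row holds sample ids and
    the body is numeric.  Duplicated ids and negative or non-numeric
    cells are rejected with an error naming the offending entry.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample metadata for a panel or screen.

    One row per sample with columns ``sample_id``, ``age_months``
    (positive integer), ``zeitgeber_time_h`` (hours since lights-on, on
    a common 24 h period), ``replicate`` (positive integer) and
    ``condition_label`` (the grouping used when collapsing samples to
    conditions; defaults to the age class).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in DESIGN_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"sample design is missing column {col!r}")
        if "condition_label" not in df.columns:
            df = df.copy()
            df["condition_label"] = df["age_months"].astype(str)
            object.__setattr__(self, "table", df)
        _check_unique(df["sample_id"].astype(str), "sample id")
        zt = df["zeitgeber_time_h"].to_numpy(dtype=float)
        if ((zt < 0) | (zt >= 24)).any():
            bad = df.loc[(zt < 0) | (zt >= 24), "sample_id"].iloc[0]
            raise FormatError(
                f"zeitgeber_time_h outside [0, 24) for sample {bad!r}"
            )
        if (df["age_months"].to_numpy(dtype=float) <= 0).any():
            raise FormatError("age_months must be positive")
        if (df["replicate"].to_numpy(dtype=float) <= 0).any():
            raise FormatError("replicate must be a positive integer")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"].astype(str))

    @property
    def age_classes(self) -> list[int]:
        return sorted(set(int(a) for a in self.table["age_months"]))

    def condition_series(self) -> pd.Series:
        """Sample -> condition label, for :func:`clrnorm.clr.clr_gene_stats`."""
        return pd.Series(
            self.table["condition_label"].to_numpy(),
            index=self.table["sample_id"].astype(str),
        )

    def samples_for_age(self, age_months: int) -> list[str]:
        mask = self.table["age_months"].astype(int) == int(age_months)
        return list(self.table.loc[mask, "sample_id"].astype(str))

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        design_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if design_ids != matrix_ids:
            raise FormatError(
                "sample design and matrix disagree: "
                f"only-in-design={sorted(design_ids - matrix_ids)[:5]}, "
                f"only-in-matrix={sorted(matrix_ids - design_ids)[:5]}"
            )

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False)


def read_sample_design(path: str | Path, delimiter: str = "\t") -> SampleDesign:
    """Read a sample design table; ``condition_label`` is optional."""
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse sample design {path}: {exc}") from exc
    return SampleDesign(df)


@dataclass(frozen=True)
class CandidateSet:
    """Candidate reference genes to be screened for stability."""

    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise FormatError("candidate set is empty")
        _check_unique(self.gene_ids, "candidate gene")

    def __iter__(self):
        return iter(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def validate_against(self, gene_universe: Iterable[str]) -> None:
        universe = set(gene_universe)
        missing = [g for g in self.gene_ids if g not in universe]
        if missing:
            raise FormatError(f"candidates absent from the gene universe: {missing}")


def read_candidate_list(path: str | Path) -> CandidateSet:
    """Read candidate gene ids, one per line (``#`` comments allowed)."""
    genes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return CandidateSet(tuple(genes))


@dataclass(frozen=True)
class StudyFoldChangeTable:
    """Long-format fold-changes of genes across independent studies.

    Columns ``gene_id``, ``study_id``, ``fold_change`` (positive;
    symmetrisation to magnitudes >= 1 happens downstream).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        for col in ("gene_id", "study_id", "fold_change"):
            if col not in df.columns:
                raise FormatError(f"fold-change table is missing column {col!r}")
        fc = df["fold_change"].to_numpy(dtype=float)
        if (fc <= 0).any() or not np.isfinite(fc).all():
            bad = df.loc[(fc <= 0) | ~np.isfinite(fc)].iloc[0]
            raise FormatError(
                f"non-positive fold-change {bad['fold_change']!r} for gene "
                f"{bad['gene_id']!r} in study {bad['study_id']!r}"
            )
        if df.duplicated(["gene_id", "study_id"]).any():
            pair = df.loc[df.duplicated(["gene_id", "study_id"])].iloc[0]
            raise FormatError(
                f"duplicate (gene, study) pair ({pair['gene_id']!r}, {pair['study_id']!r})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.table["gene_id"].astype(str).unique())

    def for_gene(self, gene_id: str) -> np.ndarray:
        sub = self.table.loc[self.table["gene_id"].astype(str) == str(gene_id)]
        if sub.empty:
            raise KeyError(f"gene {gene_id!r} has no studies in the fold-change table")
        return sub["fold_change"].to_numpy(dtype=float)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False)


def read_study_fold_changes(path: str | Path, delimiter: str = "\t") -> StudyFoldChangeTable:
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse fold-change table {path}: {exc}") from exc
    return StudyFoldChangeTable(df)


def config_digest(obj) -> str:
    """Stable short hash of a configuration mapping (for run provenance)."""
    import json

    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    delimiter: str = "\t",
    config_hash: str | None = None,
) -> list[Path]:
    """Write each result table to ``<directory>/<name>.tsv``.

    Tables round-trip losslessly through :func:`pandas.read_csv` with the
    same delimiter; an empty table yields a header-only file.  When
    ``config_hash`` is given, every file starts with a ``#`` provenance
    line (readers here skip ``#`` comments).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = directory / f"{name}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            if config_hash is not None:
                fh.write(f"# config_hash: {config_hash}\n")
            df.to_csv(fh, sep=delimiter, index=False)
        written.append(path)
    return written
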