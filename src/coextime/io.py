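"""Expression matrices, sample metadata, counts tables and gene lists.

The compendium analyses operate on a gene x sample table of FPKM values
(fragments per kilobase of transcript per million mapped fragments) that
moves through a fixed normalization cascade.  Every matrix therefore
carries a *stage* tag — one of ``FPKM``, ``log2``, ``quantile`` or
``centered`` — so downstream operations can refuse input at the wrong
stage.  This module holds the container types, plain TSV/CSV readers and
writers, the counts -> FPKM conversion, and expression-breadth summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STAGES = ("FPKM", "log2", "quantile", "centered")
LIGHT_REGIMES = ("LL", "LD", "unknown")
LIBRARY_TYPES = ("polyA", "ribodepleted", "unknown")

#: header line prefix used to serialize the stage tag with written matrices
_STAGE_PREFIX = "#stage="


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values tagged with a normalization stage.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample (or
        replicate-group) identifiers as columns.  Missing values are an
        error: an expression compendium is dense by construction.
    stage
        One of ``FPKM``, ``log2``, ``quantile``, ``centered``.  FPKM
        values must be non-negative.
    """

    values: pd.DataFrame
    stage: str = "FPKM"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")
        if self.stage == "FPKM" and (arr < 0).any():
            raise ValueError("FPKM values must be >= 0")
        self.values = pd.DataFrame(
            arr,
            index=self.values.index.astype(str).rename("gene"),
            columns=self.values.columns.astype(str).rename("sample"),
        )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], stage=self.stage)

    def with_values(self, values: pd.DataFrame, stage: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, stage=self.stage if stage is None else stage)


@dataclass
class SampleMetadata:
    """Per-sample annotations: experiment, replicate group, light regime,
    collection time (hours after dawn, in [0, 24)) and library type.

    Experiments partition samples; replicate groups partition samples
    within experiments.
    """

    table: pd.DataFrame

    _REQUIRED = ("experiment", "replicate_group")
    _OPTIONAL = {"light_regime": "unknown", "time": np.nan, "library": "unknown"}

    def __post_init__(self) -> None:
        t = self.table.copy()
        _check_unique(t.index, "sample")
        for col in self._REQUIRED:
            if col not in t.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        for col, default in self._OPTIONAL.items():
            if col not in t.columns:
                t[col] = default
        bad = set(t["light_regime"].astype(str)) - set(LIGHT_REGIMES)
        if bad - {"nan"}:
            raise ValueError(f"unknown light-regime token(s): {sorted(bad - {'nan'})}")
        t["light_regime"] = t["light_regime"].astype(str).replace("nan", "unknown")
        bad = set(t["library"].astype(str)) - set(LIBRARY_TYPES)
        if bad - {"nan"}:
            raise ValueError(f"unknown library token(s): {sorted(bad - {'nan'})}")
        t["library"] = t["library"].astype(str).replace("nan", "unknown")
        times = pd.to_numeric(t["time"], errors="raise")
        finite = times.dropna()
        if ((finite < 0) | (finite >= 24)).any():
            raise ValueError("collection times must lie in [0, 24) or be absent")
        t["time"] = times
        t.index = t.index.astype(str)
        self.table = t

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def experiment_of(self) -> pd.Series:
        return self.table["experiment"].astype(str)

    def experiments(self) -> dict[str, list[str]]:
        """Partition of sample ids by experiment, in order of appearance."""
        out: dict[str, list[str]] = {}
        for s, e in self.table["experiment"].astype(str).items():
            out.setdefault(e, []).append(s)
        return out

    def replicate_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.table["replicate_group"].astype(str).items():
            out.setdefault(g, []).append(s)
        return out

    def check_covers(self, mat: ExpressionMatrix) -> None:
        missing = [s for s in mat.samples if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    def collapsed(self) -> "SampleMetadata":
        """Metadata with one row per replicate group (after replicate averaging).

        Experiment, light regime, time and library are taken from the first
        member; members of a group must agree on the experiment.
        """
        rows = []
        for g, members in self.replicate_groups().items():
            sub = self.table.loc[members]
            if sub["experiment"].nunique() > 1:
                raise ValueError(f"replicate group {g!r} spans experiments")
            first = sub.iloc[0]
            rows.append(
                {
                    "sample": g,
                    "experiment": first["experiment"],
                    "replicate_group": g,
                    "light_regime": first["light_regime"],
                    "time": first["time"],
                    "library": first["library"],
                }
            )
        return SampleMetadata(pd.DataFrame(rows).set_index("sample"))


@dataclass
class CountsTable:
    """Integer fragment counts with per-gene transcript lengths (bp)."""

    values: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("counts table contains missing values")
        if (arr < 0).any():
            raise ValueError("counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.values = self.values.astype(np.int64)
        lengths = self.lengths.reindex(self.values.index)
        if lengths.isna().any():
            raise ValueError("every gene needs a transcript length")
        if (lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")
        self.lengths = lengths.astype(float)


@dataclass
class GeneSet:
    """A named list of gene identifiers with optional per-gene labels."""

    name: str
    members: tuple[str, ...]
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        self.members = tuple(str(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# readers / writers


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return {"tsv": "\t", "csv": ","}[fmt]
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path, fmt: str | None = None, stage: str | None = None
) -> ExpressionMatrix:
    """Read a gene x sample table (genes as rows, header row of sample ids).

    A leading ``#stage=`` comment line, as written by
    :func:`write_expression_table`, sets the stage tag unless ``stage``
    is given explicitly; otherwise the default is ``FPKM``.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    file_stage = None
    if first.startswith(_STAGE_PREFIX):
        file_stage = first[len(_STAGE_PREFIX):].strip()
        skip = 1
    df = pd.read_csv(path, sep=sep, index_col=0, skiprows=skip)
    return ExpressionMatrix(df, stage=stage or file_stage or "FPKM")


def write_expression_table(mat: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path, "w") as fh:
        fh.write(f"{_STAGE_PREFIX}{mat.stage}\n")
        mat.values.to_csv(fh, sep=sep, index_label="gene")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV keyed by a ``sample`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError("metadata file needs a 'sample' column")
    return SampleMetadata(df.set_index("sample"))


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene identifier per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """GMT-like file: one set per line, tab-separated name, description, members."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError("gene-set lines need name, description and >=1 member")
        sets.append(GeneSet(name=fields[0], members=tuple(fields[2:])))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "", *s.members]) + "\n")


# ---------------------------------------------------------------------------
# operations


def counts_to_fpkm(counts: CountsTable) -> ExpressionMatrix:
    """Convert raw fragment counts to FPKM.

    ``FPKM_gs = counts_gs * 1e9 / (L_g * N_s)`` with ``L_g`` the transcript
    length in bp and ``N_s`` the per-sample library size, taken as the
    column sum of the provided counts table.
    """
    arr = counts.values.to_numpy(dtype=float)
    n_s = arr.sum(axis=0)
    if (n_s <= 0).any():
        bad = counts.values.columns[n_s <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad[:5]}")
    lengths = counts.lengths.to_numpy()
    fpkm = arr * 1e9 / (lengths[:, None] * n_s[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        stage="FPKM",
    )


@dataclass
class ExpressionSummary:
    """Expression-breadth summary of an FPKM matrix.

    ``counts_above`` holds, for each cutoff, the number of samples in which
    each gene exceeds (strictly) that FPKM cutoff.
    """

    counts_above: pd.DataFrame  # genes x cutoffs
    gene_median: pd.Series
    sample_median: pd.Series


def expression_summary(mat: ExpressionMatrix, cutoffs: Sequence[float]) -> ExpressionSummary:
    """Per-gene breadth of expression above each FPKM cutoff (strict '>')."""
    if mat.stage != "FPKM":
        raise ValueError("expression_summary expects an FPKM-stage matrix")
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("need at least one cutoff")
    arr = mat.values.to_numpy()
    counts = pd.DataFrame(
        {c: (arr > c).sum(axis=1) for c in cutoffs}, index=mat.genes
    )
    return ExpressionSummary(
        counts_above=counts,
        gene_median=mat.values.median(axis=1),
        sample_median=mat.values.median(axis=0),
    )
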