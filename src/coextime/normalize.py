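"""The four-stage normalization cascade.

Starting from an FPKM compendium the cascade produces four datasets that
are all retained downstream:

1. replicate-averaged FPKM (arithmetic mean over each replicate group);
2. ``log2(x + 1)`` transform;
3. quantile normalization across columns, forcing every column onto the
   common distribution given by the across-column mean of sorted values;
4. per-gene mean-centering, which removes stable between-gene baseline
   differences and leaves relative (batch- and condition-driven)
   variation.

Mean-centering also records each gene's mean and standard deviation
(:class:`NormalizationStats`), which lets an external dataset be placed
on the reference scale without re-running the cascade
(:func:`center_external`): ``log2(x + 1) - m_g``.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)


@dataclass
class NormalizationStats:
    """Per-gene mean and standard deviation of the reference at the
    quantile stage (the values subtracted when centering)."""

    mean: pd.Series
    sd: pd.Series
    all_zero: pd.Index  # genes that were all-zero FPKM in the reference

    def __post_init__(self) -> None:
        if (self.sd < 0).any():
            raise ValueError("standard deviations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path) -> "NormalizationStats":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(mean=df["mean"], sd=df.get("sd", pd.Series(0.0, index=df.index)),
                   all_zero=pd.Index([]))


def average_replicates(mat: ExpressionMatrix, metadata: SampleMetadata) -> ExpressionMatrix:
    """Arithmetic mean of FPKM columns within each replicate group.

    Output columns are named by replicate-group id, ordered by first
    appearance of the group along the sample axis.
    """
    if mat.stage != "FPKM":
        raise ValueError("replicates are averaged on the FPKM scale")
    metadata.check_covers(mat)
    groups = metadata.replicate_groups()
    cols = {}
    for g, members in groups.items():
        present = [s for s in members if s in mat.values.columns]
        if not present:
            raise ValueError(f"replicate group {g!r} has no samples in the matrix")
        cols[g] = mat.values[present].mean(axis=1)
    # order groups by first appearance in the matrix's sample order
    first_pos = {g: min(mat.values.columns.get_loc(s) for s in members if s in mat.values.columns)
                 for g, members in groups.items() if g in cols}
    order = sorted(cols, key=lambda g: first_pos[g])
    return ExpressionMatrix(pd.DataFrame({g: cols[g] for g in order}), stage="FPKM")


def log2_transform(mat: ExpressionMatrix) -> ExpressionMatrix:
    """``log2(x + 1)`` with a pseudo-count of 1; stage FPKM -> log2."""
    if mat.stage != "FPKM":
        raise ValueError("log2 transform applies to the FPKM stage")
    return ExpressionMatrix(np.log2(mat.values + 1.0), stage="log2")


def _quantile_normalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy(dtype=float)
    n, s = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(arr, order, axis=0), axis=1)  # length n
    out = np.empty_like(arr)
    for j in range(s):
        col_order = order[:, j]
        vals = np.empty(n)
        vals[col_order] = ref
        # ties: average the reference values the tied ranks span
        col = arr[:, j]
        sorted_col = col[col_order]
        k = 0
        while k < n:
            m = k
            while m + 1 < n and sorted_col[m + 1] == sorted_col[k]:
                m += 1
            if m > k:
                vals[col_order[k:m + 1]] = ref[k:m + 1].mean()
            k = m + 1
        out[:, j] = vals
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common (across-column mean) distribution.

    Within-column ties all receive the mean of the reference values their
    tied ranks span (mid-rank policy).  A single-column matrix is returned
    unchanged with a warning — there is nothing to normalize across.
    """
    if mat.stage != "log2":
        raise ValueError("quantile normalization applies to the log2 stage")
    if mat.values.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return ExpressionMatrix(mat.values.copy(), stage="quantile")
    return ExpressionMatrix(_quantile_normalize_frame(mat.values), stage="quantile")


def mean_center(mat: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationStats]:
    """Subtract each gene's mean across columns; record mean and sd.

    Accepts the quantile stage (full cascade) or the log2 stage (abridged
    path for external datasets).  All-zero genes center to zero and are
    flagged in the returned stats.
    """
    if mat.stage not in ("quantile", "log2"):
        raise ValueError("mean-centering applies to the quantile or log2 stage")
    m = mat.values.mean(axis=1)
    s = mat.values.std(axis=1, ddof=0)
    centered = mat.values.sub(m, axis=0)
    all_zero = mat.genes[(mat.values == 0).all(axis=1)]
    stats = NormalizationStats(mean=m, sd=s, all_zero=all_zero)
    return ExpressionMatrix(centered, stage="centered"), stats


@dataclass
class NormalizedCascade:
    """The four retained stages plus the centering statistics."""

    rnaseq1: ExpressionMatrix  # replicate-averaged FPKM
    rnaseq2: ExpressionMatrix  # log2(x+1)
    rnaseq3: ExpressionMatrix  # quantile-normalized
    rnaseq4: ExpressionMatrix  # mean-centered
    stats: NormalizationStats

    def __iter__(self):
        return iter((self.rnaseq1, self.rnaseq2, self.rnaseq3, self.rnaseq4))


def normalize_cascade(fpkm: ExpressionMatrix, metadata: SampleMetadata) -> NormalizedCascade:
    """Run replicate averaging -> log2 -> quantile -> mean-centering."""
    r1 = average_replicates(fpkm, metadata)
    r2 = log2_transform(r1)
    r3 = quantile_normalize(r2)
    r4, stats = mean_center(r3)
    return NormalizedCascade(r1, r2, r3, r4, stats)


def center_external(fpkm_new: ExpressionMatrix, stats: NormalizationStats) -> ExpressionMatrix:
    """Place an external FPKM dataset on the reference centered scale.

    Applies ``log2(x + 1) - m_g`` per gene, restricted to the genes present
    in the reference statistics.  Genes absent from the stats are dropped
    (count logged).  This is the abridged path: it skips the quantile step,
    so values agree with the full cascade only up to the quantile-step
    deviation.
    """
    if fpkm_new.stage != "FPKM":
        raise ValueError("center_external expects an FPKM matrix")
    shared = fpkm_new.genes.intersection(stats.mean.index)
    dropped = len(fpkm_new.genes) - len(shared)
    if len(shared) == 0:
        raise ValueError("no genes shared with the normalization statistics")
    if dropped:
        log.info("center_external: dropped %d genes absent from reference stats", dropped)
    logged = np.log2(fpkm_new.values.loc[shared] + 1.0)
    centered = logged.sub(stats.mean.loc[shared], axis=0)
    return ExpressionMatrix(centered, stage="centered")
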