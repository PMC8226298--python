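"""Diurnal phase references and the molecular-timetable method.

A *phase table* assigns each rhythmic gene a diurnal phase — the hour
after dawn, in [0, 24), at which its expression peaks under light–dark
entrainment — together with a rhythmicity q-value (BH-adjusted, as
produced by rhythm detectors such as JTK_CYCLE run on dense time
courses; rhythmicity detection itself is upstream of this package).

The molecular timetable estimates the internal diurnal time of a single
transcriptome snapshot: pick *marker* genes evenly covering the phase
cycle (the most confidently rhythmic genes per phase bin), average their
mean-centered expression per bin, and read off the bin with maximal mean
expression.  In a partially synchronized culture the bin means trace a
cosine over the phase axis whose peak sits at the sample's internal time
and whose peak-to-trough amplitude scales with the fraction of cells
oscillating in phase — which is how residual synchronization of
nominally asynchronous cultures is quantified against fully entrained
reference samples.

Phases transfer across species through strict one-to-one ortholog maps:
a target species' genes inherit the reference phases, and its expression
is centered with the reference gene means so the same marker set applies.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .normalize import NormalizationStats, center_external

log = logging.getLogger(__name__)


def wrap_phase(phase):
    """Wrap an hour value onto [0, 24): a phase of 26 h equals 2 h."""
    arr = np.asarray(phase, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("phase must be finite")
    wrapped = np.mod(arr, 24.0)
    # np.mod can return exactly 24.0 for tiny negative inputs
    wrapped = np.where(wrapped >= 24.0, 0.0, wrapped)
    return float(wrapped) if np.isscalar(phase) or arr.ndim == 0 else wrapped


def circular_distance(a, b) -> np.ndarray | float:
    """Shortest separation between two hour values on the 24-h circle."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 24.0)
    out = np.minimum(d, 24.0 - d)
    return float(out) if out.ndim == 0 else out


@dataclass
class PhaseTable:
    """Gene -> (diurnal phase, rhythmicity q-value) reference."""

    table: pd.DataFrame  # index gene; columns phase, q [, secondary_phase]
    source: str = ""

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate gene ids in phase table")
        for col in ("phase", "q"):
            if col not in t.columns:
                raise ValueError(f"phase table needs a {col!r} column")
        if ((t["phase"] < 0) | (t["phase"] >= 24)).any():
            raise ValueError("phases must lie in [0, 24)")
        if ((t["q"] < 0) | (t["q"] > 1)).any():
            raise ValueError("q-values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        out = self.table.copy()
        out["source"] = self.source
        out.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def read(cls, path) -> "PhaseTable":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        source = ""
        if "source" in df.columns:
            src = df.pop("source").unique()
            source = str(src[0]) if len(src) == 1 else ""
        return cls(df, source=source)


def merge_phase_references(
    ref_a: PhaseTable, ref_b: PhaseTable, shift: float = 12.0
) -> PhaseTable:
    """Intersect two rhythmicity references after aligning time conventions.

    Reference B phases are shifted by ``shift`` hours and wrapped (the two
    source studies used dawn conventions 12 h apart).  Only genes rhythmic
    in both references are retained; the primary phase and q-value come
    from reference A, and the aligned reference-B phase is kept as
    ``secondary_phase``.
    """
    shared = ref_a.genes.intersection(ref_b.genes)
    if len(shared) == 0:
        warnings.warn("no gene rhythmic in both references; empty merged table")
        empty = pd.DataFrame(columns=["phase", "q", "secondary_phase"],
                             index=pd.Index([], name="gene"), dtype=float)
        return PhaseTable(empty, source=f"{ref_a.source}&{ref_b.source}")
    out = ref_a.table.loc[shared, ["phase", "q"]].copy()
    out["secondary_phase"] = wrap_phase(ref_b.table.loc[shared, "phase"].to_numpy() + shift)
    return PhaseTable(out, source=f"{ref_a.source}&{ref_b.source}")


@dataclass
class CircularSummary:
    """Circular mean phase (h), mean resultant length R and counts."""

    mean_phase: float | None
    resultant_length: float
    n: int
    fraction_rhythmic: float | None = None

    _R_TOL = 1e-9

    def __post_init__(self) -> None:
        if not -1e-12 <= self.resultant_length <= 1 + 1e-12:
            raise ValueError("resultant length must lie in [0, 1]")


def circular_summary(phases) -> CircularSummary:
    """Circular mean and resultant length of hour values on the 24-h circle.

    When the unit vectors cancel (R ~ 0, e.g. two antiphase genes) the
    mean direction is undefined and reported as None.
    """
    arr = np.asarray(list(phases), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one phase")
    ang = 2.0 * np.pi * arr / 24.0
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    r = float(np.hypot(c, s))
    if r < CircularSummary._R_TOL:
        return CircularSummary(mean_phase=None, resultant_length=r, n=arr.size)
    mean = wrap_phase(np.arctan2(s, c) * 24.0 / (2.0 * np.pi))
    return CircularSummary(mean_phase=float(mean), resultant_length=r, n=arr.size)


def module_phase_summary(module_genes, phase_table: PhaseTable) -> CircularSummary:
    """Rhythmic fraction and circular phase summary of a module's members.

    A gene counts as rhythmic when present in the phase table.  With no
    rhythmic member the summary carries no direction (mean None, R 0).
    """
    members = [str(g) for g in module_genes]
    if not members:
        raise ValueError("empty module")
    rhythmic = [g for g in members if g in phase_table.genes]
    frac = len(rhythmic) / len(members)
    if not rhythmic:
        return CircularSummary(mean_phase=None, resultant_length=0.0, n=0,
                               fraction_rhythmic=0.0)
    summary = circular_summary(phase_table.table.loc[rhythmic, "phase"].to_numpy())
    return CircularSummary(
        mean_phase=summary.mean_phase,
        resultant_length=summary.resultant_length,
        n=summary.n,
        fraction_rhythmic=frac,
    )


@dataclass
class PhaseOrderReport:
    """Association between a display ordering and diurnal phases."""

    table: pd.DataFrame            # gene, order_rank, phase
    correlation: float             # circular-circular (Fisher–Lee) coefficient
    abs_correlation: float
    null_percentile: float | None = None  # of |corr| within the permutation null


def _fisher_lee(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher–Lee circular–circular correlation of two angle vectors."""
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    num = np.sum(np.sin(da) * np.sin(db))
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    return float(num / den) if den > 0 else 0.0


def phase_vs_order(
    ordered_genes, phase_table: PhaseTable, n_null: int = 0, seed: int = 0
) -> PhaseOrderReport:
    """Correlate a gene ordering (e.g. the AOE display order) with phases.

    The ordering is treated as a position around a circle (rank mapped to
    [0, 2pi)), matching the circular nature of eigenvector orderings, and
    associated with the diurnal phase angle via the Fisher–Lee
    circular–circular correlation.  With ``n_null > 0``, a permutation
    null of the ordering gives the percentile of the observed |coefficient|.
    """
    ordered = [str(g) for g in ordered_genes]
    with_phase = [g for g in ordered if g in phase_table.genes]
    if len(with_phase) < 10:
        raise ValueError("need at least 10 ordered genes with phases")
    n = len(with_phase)
    ranks = np.arange(n, dtype=float)
    phases = phase_table.table.loc[with_phase, "phase"].to_numpy(dtype=float)
    a = 2.0 * np.pi * ranks / n
    b = 2.0 * np.pi * phases / 24.0
    corr = _fisher_lee(a, b)
    table = pd.DataFrame({"gene": with_phase, "order_rank": ranks.astype(int),
                          "phase": phases})
    pct = None
    if n_null > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_null)
        for i in range(n_null):
            null[i] = abs(_fisher_lee(a[rng.permutation(n)], b))
        pct = float(100.0 * np.mean(null < abs(corr)))
    return PhaseOrderReport(table=table, correlation=corr,
                           abs_correlation=abs(corr), null_percentile=pct)


# ---------------------------------------------------------------------------
# molecular timetable


@dataclass
class MarkerSet:
    """Phase-binned marker genes with their reference statistics.

    Bins are left-closed, right-open and partition [0, 24); each holds up
    to ``per_bin`` genes (the lowest-q genes of that phase bin).  Bins
    that could not be filled are flagged in ``short_bins``.
    """

    bin_width: float
    bins: dict[float, tuple[str, ...]]   # bin start -> marker gene ids
    mean: pd.Series                      # reference mean per marker gene
    sd: pd.Series
    short_bins: tuple[float, ...] = ()

    @property
    def n_markers(self) -> int:
        return sum(len(g) for g in self.bins.values())

    @property
    def bin_starts(self) -> np.ndarray:
        return np.array(sorted(self.bins), dtype=float)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0

    def all_markers(self) -> list[str]:
        return [g for start in sorted(self.bins) for g in self.bins[start]]

    def write(self, path) -> None:
        rows = []
        for start in sorted(self.bins):
            for g in self.bins[start]:
                rows.append({"gene": g, "bin_start": start,
                             "mean": self.mean.get(g, np.nan),
                             "sd": self.sd.get(g, np.nan)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def select_markers(
    phase_table: PhaseTable,
    stats: NormalizationStats,
    per_bin: int = 20,
    bin_width: float = 1.0,
    min_mean: float | None = None,
) -> MarkerSet:
    """Pick the ``per_bin`` most confidently rhythmic genes per phase bin.

    Genes are binned by phase into left-closed bins of ``bin_width`` hours
    (0.5-h bins with 20 genes each give the 960-marker configuration,
    1-h bins the 480-marker one) and sorted by ascending q-value, ties by
    gene id.  Bins with fewer than ``per_bin`` genes take all available
    and are flagged.

    ``min_mean`` drops candidate genes whose reference mean (log2 scale)
    falls below the floor before ranking: the log2(x + 1) transform
    flattens oscillation troughs of lowly expressed genes, so reliable
    phase markers should be comfortably above the pseudo-count.
    """
    if len(phase_table) == 0:
        raise ValueError("empty phase table")
    if not (0 < bin_width <= 24) or (24.0 / bin_width) % 1 != 0:
        raise ValueError("bin width must divide 24 h")
    t = phase_table.table
    if min_mean is not None:
        keep = stats.mean.reindex(t.index) >= min_mean
        t = t.loc[keep.fillna(False)]
        if t.empty:
            raise ValueError("no phase-table gene passes the expression floor")
    starts = np.arange(0.0, 24.0, bin_width)
    bin_of = np.floor(t["phase"].to_numpy() / bin_width) * bin_width
    bins: dict[float, tuple[str, ...]] = {}
    short: list[float] = []
    for start in starts:
        in_bin = t.index[bin_of == start]
        ranked = sorted(in_bin, key=lambda g: (t.at[g, "q"], g))
        chosen = tuple(ranked[:per_bin])
        if len(chosen) < per_bin:
            short.append(float(start))
        bins[float(start)] = chosen
    if short:
        log.warning("select_markers: %d bin(s) short of %d genes", len(short), per_bin)
    markers = [g for b in bins.values() for g in b]
    mean = stats.mean.reindex(markers)
    sd = stats.sd.reindex(markers)
    return MarkerSet(bin_width=bin_width, bins=bins, mean=mean, sd=sd,
                     short_bins=tuple(short))


@dataclass
class TimetableResult:
    """Per-sample molecular-timetable readout.

    ``bin_means`` holds the mean centered expression of each phase bin's
    markers (bins x samples); ``per_sample`` the derived peak/trough bins,
    internal time (peak-bin midpoint, h), amplitude (max - min of bin
    means) and peak–trough circular separation (h).
    """

    bin_means: pd.DataFrame
    per_sample: pd.DataFrame
    bin_width: float
    n_markers_used: int
    n_markers_missing: int

    @property
    def internal_time(self) -> pd.Series:
        return self.per_sample["internal_time"]

    @property
    def amplitude(self) -> pd.Series:
        return self.per_sample["amplitude"]


def timetable_profile(
    expr: ExpressionMatrix, markers: MarkerSet, scale_sd: bool = False
) -> TimetableResult:
    """Run the molecular timetable on mean-centered expression.

    For every sample, marker genes are averaged within their phase bins;
    the bin with maximal mean expression gives the internal time (its
    midpoint), the minimal bin the trough, and their difference the
    amplitude.  Ties resolve to the earliest bin.  Markers absent from
    the matrix are dropped and logged; more than 50% missing is an error.

    With ``scale_sd`` each marker is additionally divided by its reference
    standard deviation (a z-score).  This equalizes marker oscillation
    amplitudes, so every phase bin contributes comparably; without it,
    bins dominated by high-amplitude genes can pull the peak/trough
    assignment sideways.  Off by default: the reference protocol subtracts
    the mean only.
    """
    if expr.stage != "centered":
        raise ValueError("timetable input must be mean-centered expression")
    all_markers = markers.all_markers()
    present = set(expr.genes)
    missing = [g for g in all_markers if g not in present]
    if len(missing) > 0.5 * len(all_markers):
        raise ValueError(
            f"{len(missing)}/{len(all_markers)} marker genes missing from the matrix"
        )
    if missing:
        log.info("timetable_profile: dropped %d missing marker(s)", len(missing))
    starts = sorted(markers.bins)
    rows = []
    for start in starts:
        genes = [g for g in markers.bins[start] if g in present]
        if genes:
            vals = expr.values.loc[genes]
            if scale_sd:
                sd = markers.sd.reindex(genes).astype(float)
                if sd.isna().any() or (sd <= 0).any():
                    raise ValueError("sd-scaling requires positive reference sds "
                                     "for all markers")
                vals = vals.div(sd, axis=0)
            rows.append(vals.mean(axis=0))
        else:
            rows.append(pd.Series(np.nan, index=expr.samples))
    bin_means = pd.DataFrame(rows, index=pd.Index(starts, name="bin_start"))
    if bin_means.isna().any().any():
        raise ValueError("empty phase bin after dropping missing markers")
    arr = bin_means.to_numpy()
    mids = np.asarray(starts, dtype=float) + markers.bin_width / 2.0
    peak_idx = np.argmax(arr, axis=0)    # first maximal bin (earliest)
    trough_idx = np.argmin(arr, axis=0)
    amplitude = arr.max(axis=0) - arr.min(axis=0)
    internal = mids[peak_idx]
    separation = circular_distance(mids[peak_idx], mids[trough_idx])
    per_sample = pd.DataFrame(
        {
            "peak_bin": np.asarray(starts)[peak_idx],
            "trough_bin": np.asarray(starts)[trough_idx],
            "internal_time": internal,
            "amplitude": amplitude,
            "peak_trough_separation": separation,
        },
        index=expr.samples,
    )
    return TimetableResult(
        bin_means=bin_means,
        per_sample=per_sample,
        bin_width=markers.bin_width,
        n_markers_used=len(all_markers) - len(missing),
        n_markers_missing=len(missing),
    )


def estimate_sync(result: TimetableResult, reference_amplitudes) -> pd.Series:
    """Synchronization percentage per sample.

    ``sync% = 100 * A_sample / mean(A_reference)`` capped at 100, with the
    reference amplitudes taken from designated fully entrained (light–dark
    time-course) samples.  The cosine term of a partially synchronized
    culture scales linearly with the synchronized fraction, so relative
    amplitude is a direct estimator of it.
    """
    ref = np.asarray(list(reference_amplitudes), dtype=float)
    if ref.size == 0:
        raise ValueError("need at least one reference amplitude")
    denom = float(ref.mean())
    if denom <= 0:
        raise ValueError("reference amplitudes must have positive mean")
    sync = 100.0 * result.amplitude / denom
    return sync.clip(upper=100.0).rename("sync_percent")


@dataclass
class OrthologMap:
    """Strict one-to-one gene pairs between a reference and target species."""

    pairs: pd.DataFrame  # columns: reference, target

    def __post_init__(self) -> None:
        p = self.pairs
        for col in ("reference", "target"):
            if col not in p.columns:
                raise ValueError("ortholog map needs 'reference' and 'target' columns")
            if p[col].duplicated().any():
                raise ValueError(f"ortholog map not one-to-one in {col!r}")
        self.pairs = p.astype(str)

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class TransferResult:
    """Cross-species transfer output: target expression on the reference
    centered scale (genes renamed to reference ids) plus inherited phases."""

    matrix: ExpressionMatrix
    phases: PhaseTable
    n_unmapped: int
    n_nonrhythmic: int


def transfer_orthologs(
    target_fpkm: ExpressionMatrix,
    ortholog_map: OrthologMap,
    stats: NormalizationStats,
    phase_table: PhaseTable,
) -> TransferResult:
    """Project a target species onto the reference timetable.

    Target genes are restricted to those with a one-to-one ortholog whose
    reference gene is rhythmic (present in the phase table); expression is
    centered as ``log2(x + 1) - m_ref`` using the reference ortholog's
    mean, rows are renamed to the reference gene ids so the reference
    marker set resolves directly, and phases are inherited.
    """
    if target_fpkm.stage != "FPKM":
        raise ValueError("transfer expects target FPKM values")
    pairs = ortholog_map.pairs
    in_matrix = pairs["target"].isin(target_fpkm.genes)
    n_unmapped = len(target_fpkm.genes) - int(in_matrix.sum())
    pairs = pairs[in_matrix]
    rhythmic = pairs["reference"].isin(phase_table.genes) & pairs["reference"].isin(
        stats.mean.index
    )
    n_nonrhythmic = int((~rhythmic).sum())
    pairs = pairs[rhythmic]
    if pairs.empty:
        raise ValueError("no target gene maps to a rhythmic reference ortholog")
    if n_nonrhythmic:
        log.info("transfer_orthologs: dropped %d gene(s) with non-rhythmic "
                 "reference orthologs", n_nonrhythmic)
    sub = target_fpkm.values.loc[pairs["target"]].copy()
    sub.index = pd.Index(pairs["reference"], name="gene")
    renamed = ExpressionMatrix(sub, stage="FPKM")
    centered = center_external(renamed, stats)
    phases = PhaseTable(
        phase_table.table.loc[centered.genes].copy(), source=phase_table.source
    )
    return TransferResult(
        matrix=centered,
        phases=phases,
        n_unmapped=n_unmapped,
        n_nonrhythmic=n_nonrhythmic,
    )
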