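"""All-pairs Pearson correlation and correlation-matrix ordering.

Correlations are computed either between genes (each gene characterized
by its expression across samples) or between samples (each sample by its
expression across genes).  Three ordering methods reproduce the standard
correlation-display layouts: complete-linkage hierarchical clustering on
``1 - r``, the angular order of the two leading eigenvectors (AOE), and
first-principal-component loadings (FPC).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats as sstats

from .io import ExpressionMatrix, SampleMetadata

log = logging.getLogger(__name__)

ORDER_METHODS = ("hclust", "AOE", "FPC")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over genes or samples."""

    values: pd.DataFrame
    axis: str  # 'gene' | 'sample'
    zero_variance: tuple[str, ...] = ()
    ordering: np.ndarray | None = None
    method: str = "pearson"

    def __post_init__(self) -> None:
        if self.axis not in ("gene", "sample"):
            raise ValueError("axis must be 'gene' or 'sample'")
        arr = self.values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(arr).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        if arr.size and not np.allclose(np.diag(arr), 1.0):
            raise ValueError("diagonal must equal 1")

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def upper_triangle(self) -> np.ndarray:
        arr = self.values.to_numpy()
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]


def pair_count(n: int) -> int:
    """Number of unordered, non-self pairs among ``n`` items: n(n-1)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


def pcc_matrix(
    mat: ExpressionMatrix, axis: str = "gene", block_size: int = 2048
) -> CorrelationMatrix:
    """Full Pearson correlation matrix along ``axis``.

    Rows are standardized once and the correlation computed blockwise, so
    memory stays bounded by one block of rows times the full matrix; the
    result is independent of ``block_size``.  Zero-variance rows have no
    defined correlation; they are reported as 0 and flagged so downstream
    rankings stay total.
    """
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    data = mat.values if axis == "gene" else mat.values.T
    arr = data.to_numpy(dtype=float)
    n, m = arr.shape
    if m < 3:
        raise ValueError("need at least 3 observations per correlated item")
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    z = centered / safe[:, None]
    out = np.empty((n, n), dtype=float)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        out[start:stop] = z[start:stop] @ z.T
    np.clip(out, -1.0, 1.0, out=out)
    if zero.any():
        out[zero, :] = 0.0
        out[:, zero] = 0.0
        log.warning("pcc_matrix: %d zero-variance rows reported as r=0", int(zero.sum()))
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0  # exact symmetry despite float reduction order
    ids = data.index
    return CorrelationMatrix(
        pd.DataFrame(out, index=ids, columns=ids),
        axis=axis,
        zero_variance=tuple(ids[zero]),
    )


def _leaf_order_min_index(link: np.ndarray, n: int) -> np.ndarray:
    """Dendrogram leaf order with children visited lowest-leaf-first.

    Any child ordering keeps clusters contiguous; preferring the subtree
    holding the smallest original index makes the order deterministic and
    reduces to the original order when all merges tie.
    """
    children = {n + i: (int(a), int(b)) for i, (a, b, *_rest) in enumerate(link)}
    min_leaf: dict[int, int] = {}

    def _min(node: int) -> int:
        if node < n:
            return node
        if node not in min_leaf:
            a, b = children[node]
            min_leaf[node] = min(_min(a), _min(b))
        return min_leaf[node]

    order: list[int] = []
    stack = [n + len(link) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if _min(a) <= _min(b) else (b, a)
        stack.append(second)
        stack.append(first)
    return np.asarray(order, dtype=int)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # deterministic eigenvector orientation: largest-|.| component positive
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def order_matrix(corr: CorrelationMatrix, method: str = "AOE") -> np.ndarray:
    """Ordering permutation (array of positions) for display/clustering.

    ``hclust``
        leaf order of complete-linkage hierarchical clustering on the
        distance ``1 - r``.
    ``AOE``
        angular order of eigenvectors: sort by
        ``atan2(v2_i, v1_i)`` over the two leading eigenvectors of ``r``.
    ``FPC``
        sort by loadings on the first principal component of ``r``.

    Sorting ties are broken by original index (stable sort); eigenvector
    signs are fixed so the largest-magnitude component is positive.
    """
    if method not in ORDER_METHODS:
        raise ValueError(
            f"unknown ordering method {method!r}; expected one of {ORDER_METHODS}"
        )
    arr = corr.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("correlation matrix has non-finite entries")
    n = arr.shape[0]
    off = arr - np.diag(np.diag(arr))
    if np.abs(off).max(initial=0.0) < 1e-12:
        return np.arange(n)  # no structure: all orders tie, keep the original
    if method == "hclust":
        if n < 3:
            return np.arange(n)
        dist = squareform(np.clip(1.0 - arr, 0.0, None), checks=False)
        link = sch.linkage(dist, method="complete")
        return _leaf_order_min_index(link, n)
    if method == "AOE":
        w, v = np.linalg.eigh(arr)
        v1 = _fix_sign(v[:, -1])
        v2 = _fix_sign(v[:, -2]) if n > 1 else np.zeros(n)
        angles = np.arctan2(v2, v1)
        return np.argsort(angles, kind="stable")
    if method == "FPC":
        w, v = np.linalg.eigh(arr)
        load = _fix_sign(v[:, -1]) * np.sqrt(max(w[-1], 0.0))
        return np.argsort(load, kind="stable")
    raise AssertionError("unreachable")


@dataclass
class SampleCorrelationSummary:
    """Within- vs between-experiment sample correlations (diagonal excluded)."""

    intra: np.ndarray
    inter: np.ndarray
    per_experiment_mean: pd.Series
    intra_mean: float
    intra_sd: float
    inter_mean: float
    inter_sd: float
    singletons: tuple[str, ...]


def sample_correlation_summary(
    corr: CorrelationMatrix, metadata: SampleMetadata
) -> SampleCorrelationSummary:
    """Split off-diagonal sample PCCs into intra- and inter-experiment sets.

    Experiments with a single sample contribute no intra-experiment pairs
    and are reported in ``singletons``.
    """
    if corr.axis != "sample":
        raise ValueError("summary requires a sample-axis correlation matrix")
    samples = list(corr.ids)
    exp = metadata.table["experiment"].astype(str).reindex(samples)
    if exp.isna().any():
        raise ValueError("metadata missing for some correlated samples")
    arr = corr.values.to_numpy()
    labels = exp.to_numpy()
    iu = np.triu_indices(len(samples), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = arr[iu]
    intra, inter = vals[same], vals[~same]
    per_exp = {}
    for e in pd.unique(labels):
        mask = same & (labels[iu[0]] == e)
        if mask.any():
            per_exp[e] = float(vals[mask].mean())
    counts = pd.Series(labels).value_counts()
    singles = tuple(counts.index[counts == 1])
    if singles:
        log.info("sample_correlation_summary: %d single-sample experiments excluded "
                 "from intra set", len(singles))
    def _ms(x):
        return (float(np.mean(x)), float(np.std(x))) if x.size else (float("nan"), float("nan"))
    im, isd = _ms(intra)
    em, esd = _ms(inter)
    return SampleCorrelationSummary(
        intra=intra, inter=inter,
        per_experiment_mean=pd.Series(per_exp, dtype=float),
        intra_mean=im, intra_sd=isd, inter_mean=em, inter_sd=esd,
        singletons=singles,
    )


@dataclass
class PCCDistributionStats:
    """Shape of the all-pairs gene PCC distribution vs a normal reference."""

    n_pairs: int
    mean: float
    sd: float
    ks_statistic: float
    ks_pvalue: float


def pcc_distribution_stats(corr: CorrelationMatrix, seed: int = 0) -> PCCDistributionStats:
    """Upper-triangle PCCs compared (two-sample KS) with a seeded normal
    draw of matching mean, standard deviation and size."""
    if corr.axis != "gene":
        raise ValueError("distribution stats are defined on the gene axis")
    vals = corr.upper_triangle()
    mean = float(vals.mean())
    sd = float(vals.std())
    rng = np.random.default_rng(seed)
    ref = rng.normal(mean, sd, size=vals.size)
    d, p = sstats.ks_2samp(vals, ref)
    return PCCDistributionStats(
        n_pairs=int(vals.size), mean=mean, sd=sd,
        ks_statistic=float(d), ks_pvalue=float(p),
    )
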