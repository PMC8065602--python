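"""Signed weighted coexpression networks, built from scratch.

The chain is the classic one: variance/expression filtering, signed
soft-threshold adjacency ``a_ij = ((1 + r_ij)/2)**beta`` with the power
chosen by scale-free model fit, topological overlap (TOM), average-linkage
clustering of ``1 - TOM`` cut at a fixed height into modules, module
eigengenes (first principal component), eigengene-based connectivity (kME)
and locally-weighted trajectory fits of eigengenes across developmental
stages.

Everything operates on a gene × sample :class:`~neurocoex.io.ExpressionDataset`;
genes are rows throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExpressionDataset

__all__ = [
    "FilterReport", "SoftThresholdReport", "TOMatrix", "ModulePartition",
    "ModuleEigengenes", "KmeTable",
    "filter_genes", "pick_soft_threshold", "signed_adjacency", "compute_tom",
    "detect_modules", "module_eigengenes", "compute_kme", "fit_trajectory",
]

UNASSIGNED = "unassigned"


@dataclass
class FilterReport:
    retained: list[str]
    nonzero_fraction: pd.Series
    cv: pd.Series


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate power and the resulting choice.

    ``signed_r2`` is the WGCNA-style index ``-sign(slope) * R^2`` of the
    log-log regression of the degree distribution, so a well-fitting
    scale-free (decreasing) distribution scores near +1.
    """

    table: pd.DataFrame  # columns: power, signed_r2, slope, mean_k
    chosen: int
    overridden: bool = False


@dataclass
class TOMatrix:
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.genes),) * 2:
            raise ValueError("TOM shape does not match gene list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("TOM diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("TOM entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)


@dataclass
class ModulePartition:
    """Gene -> module labels (M1... by decreasing size) plus the dendrogram."""

    labels: pd.Series            # index gene, value module label or UNASSIGNED
    linkage: np.ndarray | None = None

    def module_names(self) -> list[str]:
        def key(m: str):
            tail = re.search(r"(\d+)$", m)
            return (int(tail.group(1)) if tail else -1, m)
        return sorted(set(self.labels) - {UNASSIGNED}, key=key)

    def genes_of(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


@dataclass
class ModuleEigengenes:
    me: pd.DataFrame                     # module × sample, unit-norm rows
    variance_explained: dict[str, float] = field(default_factory=dict)


@dataclass
class KmeTable:
    values: pd.DataFrame                 # gene × module
    zero_variance_genes: list[str] = field(default_factory=list)


def filter_genes(dataset: ExpressionDataset,
                 min_nonzero_fraction: float = 0.5,
                 min_cv: float = 0.3) -> tuple[ExpressionDataset, FilterReport]:
    """Expression/variability filter, then log10(x + 1) transform.

    Keeps genes with nonzero RPKM in at least half the samples and a
    coefficient of variation (sd/mean on the raw scale) above 0.3.
    """
    v = dataset.values
    if v.min() < 0:
        raise ValueError("RPKM-mode expression must be non-negative")
    nz = (v > 0).mean(axis=1)
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    keep = (nz >= min_nonzero_fraction) & (cv > min_cv)
    retained = [g for g, k in zip(dataset.genes, keep) if k]
    if len(retained) < 2:
        raise ValueError("fewer than 2 genes survive the expression filter")
    out = ExpressionDataset(
        retained, list(dataset.samples),
        np.log10(v[keep] + 1.0), dataset.metadata,
    )
    report = FilterReport(
        retained=retained,
        nonzero_fraction=pd.Series(nz, index=dataset.genes),
        cv=pd.Series(cv, index=dataset.genes),
    )
    return out, report


def _correlation(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"constant gene row at index {bad}: correlation undefined")
    return np.clip(np.corrcoef(values), -1.0, 1.0)


def signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency with zero diagonal."""
    a = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, nbins: int = 10) -> tuple[float, float]:
    """(signed R², slope) of log10 p(k) ~ log10 k over connectivity bins."""
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, nbins - 1)
    xs, ys = [], []
    for b in range(nbins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        dk = k[mask].mean()
        pk = mask.mean()
        if dk > 0 and pk > 0:
            xs.append(np.log10(dk))
            ys.append(np.log10(pk))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(dataset: ExpressionDataset,
                        powers: range = range(1, 21),
                        rsq_cut: float = 0.8,
                        override: int | None = None) -> SoftThresholdReport:
    """Choose the soft-threshold power by signed scale-free topology fit.

    The chosen power is the smallest with signed R² >= ``rsq_cut``, falling
    back to the argmax; a configured ``override`` (e.g. the 12/16 used for
    the prenatal/postnatal reference networks) is echoed instead of fitted.
    """
    if dataset.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to pick a soft threshold")
    cor = _correlation(dataset.values)
    rows = []
    for beta in powers:
        a = signed_adjacency(cor, beta)
        k = a.sum(axis=1)
        signed_r2, slope = _scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": signed_r2,
                     "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    if override is not None:
        return SoftThresholdReport(table, chosen=int(override), overridden=True)
    passing = table[table["signed_r2"] >= rsq_cut]
    if len(passing):
        chosen = int(passing["power"].iloc[0])
    else:
        chosen = int(table.loc[table["signed_r2"].idxmax(), "power"])
    return SoftThresholdReport(table, chosen=chosen)


def compute_tom(dataset: ExpressionDataset, beta: float) -> TOMatrix:
    """Signed topological overlap matrix at soft-threshold power ``beta``.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k_i the node connectivity;
    the diagonal is defined as 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = _correlation(dataset.values)
    a = signed_adjacency(cor, beta)
    return tom_from_adjacency(a, dataset.genes)


def tom_from_adjacency(a: np.ndarray, genes: list[str]) -> TOMatrix:
    k = a.sum(axis=1)
    # (A @ A)_ij sums over all u; u = i and u = j contribute 0 since diag(A) = 0
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(list(genes), tom)


def _split_cluster(dissim: np.ndarray, idx: np.ndarray, height: float,
                   max_size: int) -> list[np.ndarray]:
    """Re-cut an oversized cluster at progressively lower heights."""
    if len(idx) <= max_size:
        return [idx]
    sub = dissim[np.ix_(idx, idx)]
    link = average(squareform(sub, checks=False))
    h = height
    while h > 1e-9:
        h *= 0.75
        labels = fcluster(link, t=h, criterion="distance")
        if labels.max() > 1:
            parts = []
            for lab in np.unique(labels):
                parts.extend(_split_cluster(dissim, idx[labels == lab], h, max_size))
            return parts
    # indivisible: keep the most connected core, shed the rest
    conn = sub.sum(axis=1)  # low total dissimilarity = well connected
    order = np.argsort(conn)
    return [idx[order[:max_size]], *[idx[order[max_size:]][j:j + 1]
                                     for j in range(len(idx) - max_size)]]


def detect_modules(tom: TOMatrix, cut_height: float = 0.3,
                   min_size: int = 20, max_size: int = 1000) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM cut at a fixed height.

    Flat clusters below ``min_size`` become unassigned; clusters above
    ``max_size`` are recursively re-cut at progressively lower heights
    (truncated by connectivity rank if indivisible).  Surviving modules
    are labelled M1, M2, ... by decreasing size.
    """
    if not 0 < cut_height < 1:
        raise ValueError("cut height must lie in (0, 1)")
    dissim = 1.0 - tom.values
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    flat = fcluster(link, t=cut_height, criterion="distance")

    clusters: list[np.ndarray] = []
    for lab in np.unique(flat):
        idx = np.flatnonzero(flat == lab)
        clusters.extend(_split_cluster(dissim, idx, cut_height, max_size))
    clusters = [c for c in clusters if len(c) >= min_size]
    clusters.sort(key=lambda c: (-len(c), int(c[0])))

    labels = pd.Series(UNASSIGNED, index=tom.genes, dtype=object)
    for rank, idx in enumerate(clusters, start=1):
        labels.iloc[idx] = f"M{rank}"
    return ModulePartition(labels=labels, linkage=link)


def module_eigengenes(dataset: ExpressionDataset,
                      partition: ModulePartition) -> ModuleEigengenes:
    """First principal component of each module's standardized expression.

    Eigengenes have unit norm and are sign-aligned so they correlate
    positively with the module's mean standardized expression.
    """
    frame = dataset.to_frame()
    me_rows, varexp = {}, {}
    for module in partition.module_names():
        genes = [g for g in partition.genes_of(module) if g in frame.index]
        X = frame.loc[genes].to_numpy()
        sd = X.std(axis=1)
        if (sd == 0).any():
            dropped = [g for g, s in zip(genes, sd) if s == 0]
            warnings.warn(f"{module}: dropping zero-variance genes {dropped} "
                          "from eigengene computation", stacklevel=2)
            X = X[sd > 0]
            sd = sd[sd > 0]
        Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        me = vt[0]
        if np.corrcoef(me, Z.mean(axis=0))[0, 1] < 0:
            me = -me
        me_rows[module] = me
        varexp[module] = float(s[0] ** 2 / (s**2).sum())
    me = pd.DataFrame(me_rows, index=dataset.samples).T
    return ModuleEigengenes(me=me, variance_explained=varexp)


def compute_kme(dataset: ExpressionDataset,
                eigengenes: ModuleEigengenes) -> KmeTable:
    """Pearson correlation of every gene with every module eigengene."""
    X = dataset.values
    sd = X.std(axis=1)
    zero_var = [g for g, s in zip(dataset.genes, sd) if s == 0]
    Z = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    n = X.shape[1]
    M = eigengenes.me.to_numpy()
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1)[:, None]
    kme = (Z @ Mz.T) / n
    kme[sd == 0, :] = 0.0
    values = pd.DataFrame(np.clip(kme, -1.0, 1.0), index=dataset.genes,
                          columns=eigengenes.me.index)
    return KmeTable(values=values, zero_variance_genes=zero_var)


def fit_trajectory(eigengenes: ModuleEigengenes, metadata: pd.DataFrame,
                   module: str, span: float = 0.75,
                   period_key: str = "period_rank") -> pd.Series:
    """Loess-style fit of a module eigengene across developmental stages.

    Local linear regression with tricube weights of the eigengene on the
    stage rank; returns fitted values indexed by stage.  With fewer than 4
    distinct stages, falls back to per-stage means.
    """
    y = eigengenes.me.loc[module].to_numpy()
    x = metadata.loc[eigengenes.me.columns, period_key].to_numpy(dtype=float)
    periods = np.unique(x)
    if len(periods) < 4:
        fitted = pd.Series(y).groupby(x).mean()
        fitted.index.name = period_key
        return fitted
    smooth = lowess(y, x, frac=span, return_sorted=False)
    out = pd.Series(smooth).groupby(x).mean()
    out.index.name = period_key
    return out
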