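"""Covariate-adjusted differential expression with empirical-Bayes
moderated statistics.

One linear model per gene,

    expression ~ intercept + group + RIN + pH + age + PMI + sex

with the control group as baseline and the two disease coefficients (ED
vs control, OCD vs control) extracted as contrasts.  Per-gene residual
variances are shrunk toward a common prior (d0, s0²) estimated by
moment-matching the scaled-F distribution of the sample variances on the
log scale; the moderated t uses the posterior variance

    s~² = (d0·s0² + d·s²) / (d0 + d)

on d0 + d degrees of freedom.  This is the standard microarray
moderated-t machinery, implemented here directly so its limits (d0 -> 0
gives the ordinary t, d0 -> ∞ pools all variances) are explicit.

The modelling surface follows the Model -> fit() -> Results convention:
:class:`ModeratedLinearModel` wraps the dataset and design,
``fit()`` returns a :class:`ModeratedStats` results object with
per-contrast tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionDataset

__all__ = [
    "DesignMatrix", "LinearFits", "ModeratedStats", "CrossDisorderComparison",
    "ModeratedLinearModel", "build_design", "fit_linear", "ebayes_moderate",
    "call_degs", "compare_disorders",
]

COVARIATES = ("RIN", "pH", "age", "PMI", "sex")


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # samples × coefficients
    names: list[str]
    contrasts: list[str]        # coefficient names of the disease indicators
    samples: list[str]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")


@dataclass
class LinearFits:
    genes: list[str]
    coef: pd.DataFrame          # gene × coefficient
    sigma_sq: np.ndarray        # residual variance s² per gene
    df_residual: int
    stdev_unscaled: pd.DataFrame  # gene × coefficient (se / s)


@dataclass
class ModeratedStats:
    """Results object: moderated statistics per contrast plus the prior.

    ``tables[contrast]`` has columns logFC, t, p, p_adj, s2, s2_post.
    """

    tables: dict[str, pd.DataFrame]
    prior_df: float             # d0 (may be inf)
    prior_var: float            # s0²
    df_residual: int
    genes: list[str] = field(default_factory=list)

    def table(self, contrast: str) -> pd.DataFrame:
        return self.tables[contrast]

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["Moderated differential expression",
                 "=" * 48,
                 f"genes: {len(self.genes)}   residual df: {self.df_residual}",
                 f"prior df (d0): {self.prior_df:.4g}   "
                 f"prior variance (s0^2): {self.prior_var:.4g}"]
        for name, tab in self.tables.items():
            n_deg = int((tab["p_adj"] < alpha).sum())
            top = tab.sort_values("p").head(3)
            lines.append(f"-- contrast {name}: {n_deg} genes at "
                         f"BH-adjusted p < {alpha}")
            for g, row in top.iterrows():
                lines.append(f"   {g}: logFC={row['logFC']:+.3f} "
                             f"t={row['t']:+.2f} p_adj={row['p_adj']:.2e}")
        return "\n".join(lines)


@dataclass
class CrossDisorderComparison:
    logfc_correlation: float
    deg_counts: dict[str, int]
    overlap: int
    overlap_p: float
    background: int

    def summary(self) -> str:
        names = list(self.deg_counts)
        return (f"logFC correlation r = {self.logfc_correlation:.3f}; "
                f"DEGs {names[0]} = {self.deg_counts[names[0]]}, "
                f"{names[1]} = {self.deg_counts[names[1]]}, overlap = "
                f"{self.overlap} (hypergeometric p = {self.overlap_p:.3g}, "
                f"background {self.background})")


def build_design(metadata: pd.DataFrame, group_col: str = "group",
                 baseline: str = "control",
                 covariates: tuple[str, ...] = COVARIATES) -> DesignMatrix:
    """Treatment-coded design with the control group as baseline."""
    if group_col not in metadata.columns:
        raise ValueError(f"metadata lacks group column {group_col!r}")
    groups = metadata[group_col].astype(str)
    levels = [baseline] + sorted(set(groups) - {baseline})
    if baseline not in set(groups) or len(levels) < 2:
        raise ValueError("group must have >= 2 levels including the baseline")
    cols = {"intercept": np.ones(len(metadata))}
    for lev in levels[1:]:
        cols[f"group[{lev}]"] = (groups == lev).to_numpy(dtype=float)
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"metadata lacks covariate {cov!r}")
        col = metadata[cov].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {cov!r} is constant: design would be "
                             "rank deficient")
        cols[cov] = col
    X = np.column_stack(list(cols.values()))
    return DesignMatrix(matrix=X, names=list(cols),
                        contrasts=[f"group[{lev}]" for lev in levels[1:]],
                        samples=list(metadata.index))


def fit_linear(dataset: ExpressionDataset, design: DesignMatrix) -> LinearFits:
    """Gene-wise ordinary least squares against the shared design."""
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than coefficients ({p})")
    Y = dataset.values  # genes × samples
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv            # genes × p
    resid = Y - beta @ X.T
    df = n - p
    sigma_sq = (resid**2).sum(axis=1) / df
    unscaled = np.sqrt(np.diag(xtx_inv))
    return LinearFits(
        genes=list(dataset.genes),
        coef=pd.DataFrame(beta, index=dataset.genes, columns=design.names),
        sigma_sq=sigma_sq,
        df_residual=df,
        stdev_unscaled=pd.DataFrame(np.tile(unscaled, (len(dataset.genes), 1)),
                                    index=dataset.genes, columns=design.names),
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _fit_f_dist(sigma_sq: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0²) of the scaled-F model for sample variances.

    Matches mean and variance of log s² to their digamma/trigamma
    expressions; an excess log-variance no larger than trigamma(df/2)
    yields d0 = ∞ (all genes share one variance).
    """
    s2 = np.maximum(sigma_sq, 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                         - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(fits: LinearFits, contrasts: list[str] | None = None,
                    prior_df: float | None = None) -> ModeratedStats:
    """Empirical-Bayes moderated t statistics for the disease contrasts.

    ``prior_df`` overrides the estimated d0 (0 switches the prior off and
    recovers ordinary t; ``np.inf`` pools all gene variances at s0²).
    """
    if len(fits.genes) < 10 and prior_df is None:
        raise ValueError("prior estimation needs at least 10 genes")
    if contrasts is None:
        contrasts = [c for c in fits.coef.columns if c.startswith("group[")]
    d = fits.df_residual
    if prior_df is None:
        d0, s0_sq = _fit_f_dist(fits.sigma_sq, d)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_f_dist(fits.sigma_sq, d)
    s2 = fits.sigma_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = d
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    tables = {}
    for con in contrasts:
        logfc = fits.coef[con].to_numpy()
        se = fits.stdev_unscaled[con].to_numpy() * np.sqrt(s2_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, logfc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        from .enrich import bh_adjust  # local import to avoid a cycle
        tables[_contrast_label(con)] = pd.DataFrame(
            {"logFC": logfc, "t": t, "p": p, "p_adj": bh_adjust(p),
             "s2": s2, "s2_post": s2_post}, index=fits.genes)
    return ModeratedStats(tables=tables, prior_df=d0, prior_var=s0_sq,
                          df_residual=d, genes=list(fits.genes))


def _contrast_label(coef_name: str) -> str:
    if coef_name.startswith("group[") and coef_name.endswith("]"):
        return coef_name[len("group["):-1]
    return coef_name


def call_degs(stats_: ModeratedStats, alpha: float = 0.05) -> dict[str, list[str]]:
    """Genes with BH-adjusted p below ``alpha``, per contrast."""
    return {con: list(tab.index[tab["p_adj"] < alpha])
            for con, tab in stats_.tables.items()}


def compare_disorders(stats_: ModeratedStats,
                      contrast_a: str | None = None,
                      contrast_b: str | None = None,
                      alpha: float = 0.05) -> CrossDisorderComparison:
    """Convergence of the two disorders' expression alterations.

    Pearson correlation of the full logFC vectors, plus the overlap of
    the two DEG lists scored by an upper-tail hypergeometric test against
    the shared tested-gene background.
    """
    names = list(stats_.tables)
    if contrast_a is None or contrast_b is None:
        contrast_a, contrast_b = names[0], names[1]
    ta, tb = stats_.tables[contrast_a], stats_.tables[contrast_b]
    r = float(np.corrcoef(ta["logFC"], tb["logFC"])[0, 1])
    degs = call_degs(stats_, alpha)
    da, db = set(degs[contrast_a]), set(degs[contrast_b])
    N = len(stats_.genes)
    overlap = len(da & db)
    p = float(stats.hypergeom.sf(overlap - 1, N, len(da), len(db)))
    return CrossDisorderComparison(
        logfc_correlation=r,
        deg_counts={contrast_a: len(da), contrast_b: len(db)},
        overlap=overlap, overlap_p=min(p, 1.0), background=N)


class ModeratedLinearModel:
    """Moderated linear model for a case/control expression dataset.

    Parameters
    ----------
    dataset:
        Gene × sample expression with group and covariate metadata.
    design:
        Optional pre-built design; by default built from the metadata with
        the control group as baseline and the standard covariates.
    """

    def __init__(self, dataset: ExpressionDataset,
                 design: DesignMatrix | None = None) -> None:
        self.dataset = dataset
        self.design = design if design is not None else build_design(dataset.metadata)

    @classmethod
    def from_dataframe(cls, expression: pd.DataFrame,
                       metadata: pd.DataFrame) -> "ModeratedLinearModel":
        ds = ExpressionDataset(list(expression.index), list(expression.columns),
                               expression.to_numpy(dtype=float), metadata)
        return cls(ds)

    def fit(self, prior_df: float | None = None) -> ModeratedStats:
        fits = fit_linear(self.dataset, self.design)
        return ebayes_moderate(fits, prior_df=prior_df)
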