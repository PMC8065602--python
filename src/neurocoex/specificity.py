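"""Expression-weighted specificity and bootstrap enrichment tests.

Specificity of gene g in condition c is its mean expression in c divided
by the sum of its mean expression over all conditions, so each gene's row
sums to one.  The enrichment question — does a gene set sit higher in a
condition than chance — is answered by comparing the set's mean
specificity with B random same-size draws from a background list; the
reported p is (r + 1)/(B + 1) with r the number of draws at least as
extreme, so p can never be zero and the floor at B = 10,000 corresponds
to "p < 1e-4".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = ["SpecificityMatrix", "BootstrapResult", "build_specificity",
           "bootstrap_enrichment", "epoch_enrichment"]


@dataclass
class SpecificityMatrix:
    """Row-stochastic gene × condition matrix of expression proportions."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.min() < 0 or v.max() > 1 + 1e-9:
            raise ValueError("specificity entries must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("specificity rows must sum to 1")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class BootstrapResult:
    condition: str
    observed: float       # mean specificity of the target set
    fold: float           # observed / mean of bootstrap means
    p: float              # (r + 1) / (B + 1)
    n_bootstrap: int
    seed: int | None = None


def build_specificity(dataset: ExpressionDataset,
                      condition_key: str) -> SpecificityMatrix:
    """Condition means followed by row normalization.

    Genes with zero expression in every condition are dropped with a
    warning (their specificity is undefined).
    """
    if condition_key not in dataset.metadata.columns:
        raise ValueError(f"metadata has no column {condition_key!r}")
    groups = dataset.metadata[condition_key]
    conditions = list(pd.unique(groups))
    if len(conditions) < 2:
        raise ValueError("specificity is degenerate with a single condition")
    frame = dataset.to_frame()
    means = pd.concat(
        {c: frame.loc[:, groups[groups == c].index].mean(axis=1)
         for c in conditions}, axis=1)
    totals = means.sum(axis=1)
    dead = totals == 0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} all-zero genes from the "
                      "specificity matrix", stacklevel=2)
        means, totals = means[~dead], totals[~dead]
    return SpecificityMatrix(means.div(totals, axis=0))


def bootstrap_enrichment(spec: SpecificityMatrix, target: Sequence[str],
                         background: Sequence[str], n_bootstrap: int = 10_000,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None
                         ) -> list[BootstrapResult]:
    """Bootstrap test of the target set's mean specificity per condition.

    Random same-size gene sets are drawn from the background without
    replacement (a gene set cannot repeat a gene); one family of draws is
    scored against every condition, as in expression-weighted cell-type
    enrichment.
    """
    target = list(dict.fromkeys(target))
    bg = [g for g in dict.fromkeys(background) if g in spec.values.index]
    target = [g for g in target if g in spec.values.index]
    if len(target) < 2:
        raise ValueError("target set needs at least 2 genes present in the matrix")
    if len(target) > len(bg):
        raise ValueError("target set is larger than the background")
    if rng is None:
        rng = np.random.default_rng(seed)
    V = spec.values.loc[bg].to_numpy()
    obs = spec.values.loc[target].to_numpy().mean(axis=0)

    n, s = len(bg), len(target)
    # vectorized sampling without replacement within each draw
    keys = rng.random((n_bootstrap, n))
    picks = np.argpartition(keys, s - 1, axis=1)[:, :s]
    boot = V[picks].mean(axis=1)  # n_bootstrap × n_conditions

    results = []
    for j, cond in enumerate(spec.conditions):
        r = int((boot[:, j] >= obs[j]).sum())
        mean_boot = float(boot[:, j].mean())
        results.append(BootstrapResult(
            condition=cond, observed=float(obs[j]),
            fold=float(obs[j] / mean_boot) if mean_boot > 0 else np.inf,
            p=(r + 1) / (n_bootstrap + 1),
            n_bootstrap=n_bootstrap, seed=seed))
    return results


def epoch_enrichment(spec: SpecificityMatrix, target: Sequence[str],
                     background: Sequence[str] | None = None,
                     n_bootstrap: int = 10_000, seed: int | None = None,
                     rng: np.random.Generator | None = None
                     ) -> list[BootstrapResult]:
    """Stage-wise bootstrap enrichment (the matrix columns are the stages)."""
    if background is None:
        background = spec.genes
    return bootstrap_enrichment(spec, target, background,
                                n_bootstrap=n_bootstrap, seed=seed, rng=rng)
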