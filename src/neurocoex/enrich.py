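"""Over-representation statistics: Fisher module enrichment, hypergeometric
gene-set tests, Benjamini-Hochberg correction, negative controls and the
primary-module selection rule.

The background for module enrichment is the full network gene universe
(every gene that survived the expression filter, unassigned genes
included); risk genes are assumed to be restricted to that universe
beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexnet import ModulePartition
from .io import GeneSetCollection
from .riskgenes import RiskGeneSet
from .specificity import BootstrapResult

__all__ = [
    "ContingencyTable", "EnrichmentResult",
    "fisher_module_enrichment", "hypergeom_ora", "bh_adjust",
    "negative_control", "select_primary_module",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts for a risk-set × module test.

    a = risk ∩ module, b = risk \\ module, c = module \\ risk,
    d = background \\ (risk ∪ module).
    """

    a: int
    b: int
    c: int
    d: int
    background: str = "network universe"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def odds_ratio(self) -> float:
        """Sample odds ratio with Haldane 0.5 correction when a cell is 0."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


@dataclass
class EnrichmentResult:
    unit: str
    odds_ratio: float
    p: float
    p_adj: float
    counts: ContingencyTable | None = None
    is_top: bool = False


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fisher_module_enrichment(riskset: RiskGeneSet,
                             partition: ModulePartition,
                             alternative: str = "two-sided"
                             ) -> list[EnrichmentResult]:
    """Fisher's exact test of risk genes against every module.

    Background = all partitioned genes including unassigned ones.  BH
    correction is applied across modules, and the minimal-p module is
    flagged.
    """
    universe = set(partition.labels.index)
    risk = set(riskset.genes) & universe
    if not risk:
        warnings.warn(f"empty {riskset.disorder} risk set after restriction "
                      "to the network universe", stacklevel=2)
        return []
    results = []
    for module in partition.module_names():
        members = set(partition.genes_of(module))
        a = len(risk & members)
        b = len(risk - members)
        c = len(members - risk)
        d = len(universe) - a - b - c
        table = ContingencyTable(a, b, c, d)
        p = float(stats.fisher_exact([[a, b], [c, d]],
                                     alternative=alternative)[1])
        results.append(EnrichmentResult(module, table.odds_ratio(),
                                        p, p_adj=np.nan, counts=table))
    adj = bh_adjust([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    if results:
        results[int(np.argmin([r.p for r in results]))].is_top = True
    return results


def hypergeom_ora(query: Sequence[str], sets: GeneSetCollection,
                  background: Sequence[str], min_size: int = 10,
                  report_min: int = 20, report_max: int = 500,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation across gene sets.

    Sets are intersected with the background; sets of size <= ``min_size``
    are dropped before testing.  The returned table carries BH-adjusted
    p-values for all tested sets plus a ``reported`` flag implementing the
    reporting filter (adjusted p < alpha and ``report_min`` < size <
    ``report_max``).
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    offenders = [g for g in query if g not in bg_set]
    if offenders:
        raise ValueError(f"query genes outside the background: {offenders[:5]}")
    q = set(query)
    N, n = len(bg), len(q)
    rows = []
    for name, (desc, members) in sets.items():
        S = set(members) & bg_set
        K = len(S)
        if K <= min_size:
            continue
        k = len(q & S)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "size": K, "overlap": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"])
        df["reported"] = ((df["p_adj"] < alpha)
                          & (df["size"] > report_min) & (df["size"] < report_max))
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["p_adj"] = []
        df["reported"] = []
    return df


def negative_control(control_sets: Sequence[Sequence[str]],
                     partition: ModulePartition,
                     modules: Sequence[str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Nominal Fisher p of control gene sets in the disease-enriched modules.

    A control set passes when its nominal p exceeds ``alpha`` — i.e. sets
    unrelated to the disorder (height/BMI analogues, or random draws)
    should show no enrichment.
    """
    if modules is None:
        modules = partition.module_names()
    rows = []
    for i, genes in enumerate(control_sets):
        cs = RiskGeneSet(f"control{i}", list(dict.fromkeys(genes)))
        for res in fisher_module_enrichment(cs, partition):
            if res.unit in set(modules):
                rows.append({"control_set": cs.disorder, "module": res.unit,
                             "odds_ratio": res.odds_ratio, "p": res.p,
                             "passes": res.p > alpha})
    return pd.DataFrame(rows,
                        columns=["control_set", "module", "odds_ratio", "p",
                                 "passes"])


def select_primary_module(module_prenatal: str, module_postnatal: str,
                          overlap_specificity: Sequence[BootstrapResult],
                          epoch_of: dict[str, str] | None = None,
                          alpha: float = 0.05) -> dict:
    """Pick the epoch-primary module from the overlap's stage enrichment.

    ``overlap_specificity`` holds bootstrap results of the two modules'
    gene intersection across developmental stages.  Each epoch's evidence
    is its best (lowest-p among fold > 1) stage result; the module of the
    significant epoch wins, ties or double null give "undetermined".
    """
    if not overlap_specificity:
        return {"primary": "undetermined", "reason": "empty intersection"}
    if epoch_of is None:
        epoch_of = {c: ("prenatal" if i < len(overlap_specificity) // 2
                        else "postnatal")
                    for i, c in enumerate(r.condition for r in overlap_specificity)}
    best: dict[str, BootstrapResult | None] = {"prenatal": None, "postnatal": None}
    for r in overlap_specificity:
        epoch = epoch_of.get(r.condition)
        if epoch is None or r.fold <= 1.0:
            continue
        if best[epoch] is None or r.p < best[epoch].p:
            best[epoch] = r
    sig = {e: r for e, r in best.items() if r is not None and r.p < alpha}
    out = {"prenatal_best": best["prenatal"], "postnatal_best": best["postnatal"]}
    if not sig:
        out.update(primary="undetermined", reason="no epoch significant")
        return out
    if len(sig) == 2 and np.isclose(sig["prenatal"].p, sig["postnatal"].p) \
            and np.isclose(sig["prenatal"].fold, sig["postnatal"].fold):
        out.update(primary="undetermined", reason="tie", tie=True)
        return out
    epoch = min(sig, key=lambda e: (sig[e].p, -sig[e].fold))
    out.update(
        primary=module_prenatal if epoch == "prenatal" else module_postnatal,
        epoch=epoch, reason=f"{epoch} fold {sig[epoch].fold:.3g} "
                            f"p {sig[epoch].p:.3g}")
    return out
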