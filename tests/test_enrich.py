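import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neurocoex.coexnet import ModulePartition, UNASSIGNED
from neurocoex.enrich import (ContingencyTable, bh_adjust,
                              fisher_module_enrichment, hypergeom_ora,
                              negative_control, select_primary_module)
from neurocoex.io import GeneSetCollection
from neurocoex.riskgenes import RiskGeneSet
from neurocoex.specificity import BootstrapResult


def exact_fisher_two_sided(a, b, c, d):
    """Enumeration oracle: sum hypergeometric probabilities <= P(observed)."""
    n_row, K, N = a + b, a + c, a + b + c + d
    lo, hi = max(0, n_row + K - N), min(n_row, K)
    probs = {x: stats.hypergeom.pmf(x, N, K, n_row) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def partition_from(labels_dict):
    return ModulePartition(labels=pd.Series(labels_dict, dtype=object))


class TestContingencyAndFisher:
    def test_closed_form_odds_ratio(self):
        assert ContingencyTable(5, 5, 5, 85).odds_ratio() == 17.0

    def test_haldane_correction_on_zero_cell(self):
        t = ContingencyTable(0, 10, 5, 85)
        assert t.odds_ratio() == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))

    @pytest.mark.parametrize("seed", range(20))
    def test_fisher_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            a, b, c, d = rng.integers(0, 9, 4)
            if a + b + c + d <= 30 and (a + b) and (a + c):
                break
        p_scipy = stats.fisher_exact([[a, b], [c, d]])[1]
        assert p_scipy == pytest.approx(
            exact_fisher_two_sided(a, b, c, d), abs=1e-12)

    def test_module_enrichment_flags_planted_module(self):
        labels = {f"m{i}": "M1" for i in range(20)}
        labels.update({f"x{i}": "M2" for i in range(20)})
        labels.update({f"b{i}": UNASSIGNED for i in range(60)})
        part = partition_from(labels)
        risk = RiskGeneSet("AN", [f"m{i}" for i in range(8)]
                           + ["x0", "b0", "b1", "b2"])
        res = fisher_module_enrichment(risk, part)
        by_mod = {r.unit: r for r in res}
        assert by_mod["M1"].is_top and by_mod["M1"].p < 0.01
        assert by_mod["M1"].counts.a == 8
        assert by_mod["M1"].counts.d == 100 - 8 - 4 - 12
        adj = bh_adjust([r.p for r in res])
        assert [r.p_adj for r in res] == pytest.approx(list(adj))

    def test_empty_risk_set_warns(self):
        part = partition_from({f"g{i}": "M1" for i in range(25)})
        with pytest.warns(UserWarning):
            assert fisher_module_enrichment(RiskGeneSet("AN", []), part) == []


class TestBh:
    def test_forced_equal_adjustment(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 40)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestOra:
    def test_query_inside_set_with_full_background(self):
        genes = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection({"S": ("d", genes)})
        df = hypergeom_ora(genes[:5], sets, genes, min_size=10)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_minimal_p(self):
        genes = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection({"S": ("d", genes[:5]),
                                  "BIG": ("d", genes)})
        df = hypergeom_ora(genes[:5], sets, genes, min_size=4)
        row = df[df["set"] == "S"].iloc[0]
        assert row["p"] == pytest.approx(1.0 / math.comb(20, 5), rel=1e-9)

    def test_small_sets_dropped_pre_test(self):
        genes = [f"g{i}" for i in range(40)]
        sets = GeneSetCollection({"TINY": ("d", genes[:10]),
                                  "OK": ("d", genes[:11])})
        df = hypergeom_ora(genes[:5], sets, genes, min_size=10)
        assert list(df["set"]) == ["OK"]

    def test_planted_set_attains_minimal_p(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        module = genes[:30]
        sets = {"planted": ("d", module)}
        for j in range(5):
            sets[f"rand{j}"] = ("d", list(rng.choice(genes, 30, replace=False)))
        df = hypergeom_ora(module, GeneSetCollection(sets), genes)
        assert df.iloc[0]["set"] == "planted"

    def test_query_outside_background_is_error(self):
        sets = GeneSetCollection({"S": ("d", ["a", "b"])})
        with pytest.raises(ValueError, match="zz"):
            hypergeom_ora(["zz"], sets, ["a", "b"])


class TestNegativeControl:
    def test_risk_set_itself_fails(self):
        labels = {f"m{i}": "M1" for i in range(30)}
        labels.update({f"b{i}": UNASSIGNED for i in range(170)})
        part = partition_from(labels)
        rep = negative_control([[f"m{i}" for i in range(20)]], part,
                               modules=["M1"])
        assert not rep["passes"].iloc[0]

    def test_random_sets_pass(self):
        rng = np.random.default_rng(3)
        labels = {f"g{i}": ("M1" if i < 40 else UNASSIGNED)
                  for i in range(400)}
        part = partition_from(labels)
        sets = [list(rng.choice([f"g{i}" for i in range(400)], 30,
                                replace=False)) for _ in range(10)]
        rep = negative_control(sets, part, modules=["M1"])
        assert rep["passes"].mean() >= 0.8

    def test_empty_control_list(self):
        part = partition_from({f"g{i}": "M1" for i in range(25)})
        assert negative_control([], part).empty


def boot(cond, fold, p):
    return BootstrapResult(condition=cond, observed=0.2, fold=fold, p=p,
                           n_bootstrap=1000)


class TestPrimaryModule:
    EPOCHS = {f"P{i}": ("prenatal" if i <= 4 else "postnatal")
              for i in range(1, 9)}

    def test_prenatal_significant_wins(self):
        res = [boot("P2", 1.21, 1e-4)] + [boot(f"P{i}", 0.9, 1.0)
                                          for i in (5, 6, 7, 8)]
        out = select_primary_module("preM6", "postM17", res,
                                    epoch_of=self.EPOCHS)
        assert out["primary"] == "preM6" and out["epoch"] == "prenatal"

    def test_neither_significant_undetermined(self):
        res = [boot("P2", 1.2, 0.3), boot("P6", 1.1, 0.6)]
        out = select_primary_module("a", "b", res, epoch_of=self.EPOCHS)
        assert out["primary"] == "undetermined"

    def test_exact_tie_flagged(self):
        res = [boot("P2", 1.5, 0.001), boot("P6", 1.5, 0.001)]
        out = select_primary_module("a", "b", res, epoch_of=self.EPOCHS)
        assert out["primary"] == "undetermined" and out.get("tie")

    def test_empty_results_undetermined(self):
        out = select_primary_module("a", "b", [])
        assert out["primary"] == "undetermined"

    def test_double_significance_lower_p_wins(self):
        res = [boot("P2", 1.3, 0.001), boot("P6", 1.2, 0.02)]
        out = select_primary_module("pre", "post", res, epoch_of=self.EPOCHS)
        assert out["primary"] == "pre"
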