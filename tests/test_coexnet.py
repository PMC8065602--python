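import numpy as np
import pandas as pd
import pytest

from neurocoex import coexnet
from neurocoex.coexnet import (UNASSIGNED, TOMatrix, compute_kme, compute_tom,
                               detect_modules, filter_genes, fit_trajectory,
                               module_eigengenes, pick_soft_threshold,
                               signed_adjacency, tom_from_adjacency)
from tests.conftest import make_dataset


def brute_force_tom(values, beta):
    """Triple-loop TOM oracle, straight from the definition."""
    cor = np.corrcoef(values)
    n = len(cor)
    a = ((1 + cor) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestFilterGenes:
    def test_filter_rules_and_transform(self):
        values = np.array([
            [0.0, 0.0, 0.0, 0.0],    # all zero -> removed
            [5.0, 5.0, 5.0, 5.0],    # CV = 0 -> removed
            [0.0, 0.0, 10.0, 10.0],  # nonzero frac 0.5, CV = 1.1547 -> kept
            [9.0, 11.0, 10.0, 10.0],  # CV ~ 0.08 -> removed
            [0.0, 30.0, 1.0, 9.0],   # kept
        ])
        out, report = filter_genes(make_dataset(values))
        assert out.genes == ["g2", "g4"]
        assert report.cv["g2"] == pytest.approx(5.7735 / 5, abs=1e-4)
        np.testing.assert_allclose(out.values[0], np.log10(values[2] + 1))

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            filter_genes(make_dataset(np.zeros((3, 4))))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(make_dataset(np.array([[-1.0, 2.0]])))


class TestSoftThreshold:
    def test_override_echoes_configured_power(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.random((30, 10)))
        rep = pick_soft_threshold(ds, override=12)
        assert rep.chosen == 12 and rep.overridden

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        values = rng.random((40, 12))
        a = pick_soft_threshold(make_dataset(values))
        b = pick_soft_threshold(make_dataset(values))
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.chosen == b.chosen

    def test_scale_free_planted_data_passes_fit(self):
        # heavy-tailed gene-factor coupling yields a connectivity continuum
        rng = np.random.default_rng(1)
        n, s = 600, 60
        lam = rng.uniform(0, 1, n) ** 3
        F = rng.standard_normal(s)
        values = lam[:, None] * F + rng.standard_normal((n, s)) * 0.4
        rep = pick_soft_threshold(make_dataset(values))
        assert 4 <= rep.chosen <= 20
        row = rep.table[rep.table["power"] == rep.chosen].iloc[0]
        assert row["signed_r2"] >= 0.8

    def test_constant_gene_is_error(self):
        values = np.vstack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="constant"):
            pick_soft_threshold(make_dataset(values))


class TestTom:
    def test_perfect_correlation_gives_tom_one(self):
        base = np.arange(5.0)
        values = np.vstack([base, 2 * base + 1, 3 * base - 2])
        tom = compute_tom(make_dataset(values), beta=6)
        np.testing.assert_allclose(tom.values, np.ones((3, 3)), atol=1e-10)

    def test_two_genes_tom_equals_adjacency(self):
        rng = np.random.default_rng(3)
        values = rng.random((2, 8))
        beta = 4
        tom = compute_tom(make_dataset(values), beta)
        a = signed_adjacency(np.corrcoef(values), beta)
        assert tom.values[0, 1] == pytest.approx(a[0, 1], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        values = rng.random((n, 10))
        beta = int(rng.integers(1, 13))
        tom = compute_tom(make_dataset(values), beta)
        np.testing.assert_allclose(tom.values, brute_force_tom(values, beta),
                                   atol=1e-12)

    def test_gene_permutation_permutes_tom(self):
        rng = np.random.default_rng(4)
        values = rng.random((10, 12))
        tom = compute_tom(make_dataset(values), 6)
        perm = rng.permutation(10)
        tom_p = compute_tom(make_dataset(values[perm]), 6)
        np.testing.assert_allclose(tom_p.values,
                                   tom.values[np.ix_(perm, perm)], atol=1e-12)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            TOMatrix(["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            TOMatrix(["a", "b"], np.array([[0.5, 0.2], [0.2, 1.0]]))


class TestDetectModules:
    def _planted_tom(self, sizes, within=0.9, between=0.01):
        n = sum(sizes)
        tom = np.full((n, n), between)
        start = 0
        for s in sizes:
            tom[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(tom, 1.0)
        return TOMatrix([f"g{i}" for i in range(n)], tom)

    def test_two_planted_blocks_recovered_exactly(self):
        tom = self._planted_tom([30, 30])
        part = detect_modules(tom, cut_height=0.3, min_size=20)
        assert part.sizes().to_dict() == {"M1": 30, "M2": 30}
        assert len(set(part.labels.iloc[:30])) == 1
        assert len(set(part.labels.iloc[30:])) == 1

    def test_all_disconnected_unassigned(self):
        n = 25
        tom = TOMatrix([f"g{i}" for i in range(n)], np.eye(n))
        part = detect_modules(tom, 0.3, min_size=20)
        assert (part.labels == UNASSIGNED).all()

    def test_min_size_larger_than_n(self):
        tom = self._planted_tom([15])
        part = detect_modules(tom, 0.3, min_size=20)
        assert (part.labels == UNASSIGNED).all()

    def test_max_size_split_or_truncation(self):
        tom = self._planted_tom([60], within=0.95)
        part = detect_modules(tom, 0.3, min_size=5, max_size=40)
        assert all(s <= 40 for s in part.sizes())

    def test_bad_cut_height(self):
        with pytest.raises(ValueError):
            detect_modules(self._planted_tom([30]), cut_height=1.5)

    def test_labels_ordered_by_size(self):
        tom = self._planted_tom([25, 45])
        part = detect_modules(tom, 0.3, min_size=20)
        assert len(part.genes_of("M1")) == 45
        assert len(part.genes_of("M2")) == 25


class TestEigengenesAndKme:
    def test_single_gene_module_me_is_zscored_profile(self):
        rng = np.random.default_rng(5)
        values = rng.random((1, 9))
        ds = make_dataset(values)
        part = coexnet.ModulePartition(
            labels=pd.Series(["M1"], index=ds.genes, dtype=object))
        me = module_eigengenes(ds, part)
        z = (values[0] - values[0].mean()) / values[0].std()
        r = np.corrcoef(me.me.loc["M1"], z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(me.me.loc["M1"]) == pytest.approx(1.0)

    def test_two_perfectly_correlated_genes_variance_explained_one(self):
        base = np.arange(8.0)
        ds = make_dataset(np.vstack([base, 3 * base + 2]))
        part = coexnet.ModulePartition(
            labels=pd.Series(["M1", "M1"], index=ds.genes, dtype=object))
        me = module_eigengenes(ds, part)
        assert me.variance_explained["M1"] == pytest.approx(1.0)

    def test_planted_module_me_tracks_latent_factor(self, dev_tiny, tiny_spec):
        dataset, truth = dev_tiny
        logged, _ = filter_genes(dataset)
        labels = pd.Series(
            [truth.module_of[g] if truth.module_of[g].startswith("mod")
             else UNASSIGNED for g in logged.genes],
            index=logged.genes, dtype=object).replace(
            {f"mod{i}": f"M{i + 1}" for i in range(8)})
        part = coexnet.ModulePartition(labels=labels)
        me = module_eigengenes(logged, part)
        kme = compute_kme(logged, me)
        for i in range(8):
            genes = [g for g in logged.genes
                     if truth.module_of[g] == f"mod{i}"]
            mean_profile = logged.to_frame().loc[genes].mean()
            r = np.corrcoef(me.me.loc[f"M{i + 1}"], mean_profile)[0, 1]
            assert abs(r) >= 0.95
            # the top-kME gene for each module belongs to it
            top_gene = kme.values[f"M{i + 1}"].idxmax()
            assert truth.module_of[top_gene] == f"mod{i}"

    def test_kme_sign_identities(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(10)
        ds = make_dataset(np.vstack([base, -base, base * 2]))
        part = coexnet.ModulePartition(
            labels=pd.Series(["M1", UNASSIGNED, UNASSIGNED],
                             index=ds.genes, dtype=object))
        me = module_eigengenes(ds, part)
        kme = compute_kme(ds, me)
        assert kme.values.loc["g0", "M1"] == pytest.approx(1.0, abs=1e-10)
        assert kme.values.loc["g1", "M1"] == pytest.approx(-1.0, abs=1e-10)

    def test_zero_variance_gene_flagged_zero(self):
        base = np.arange(6.0)
        ds = make_dataset(np.vstack([base, np.full(6, 3.0)]))
        part = coexnet.ModulePartition(
            labels=pd.Series(["M1", UNASSIGNED], index=ds.genes, dtype=object))
        me = module_eigengenes(ds, part)
        kme = compute_kme(ds, me)
        assert kme.values.loc["g1", "M1"] == 0.0
        assert kme.zero_variance_genes == ["g1"]


class TestTrajectory:
    def _me(self, values, ranks):
        me = coexnet.ModuleEigengenes(
            me=pd.DataFrame([values], index=["M1"],
                            columns=[f"s{i}" for i in range(len(values))]))
        meta = pd.DataFrame({"period_rank": ranks},
                            index=[f"s{i}" for i in range(len(values))])
        return me, meta

    def test_constant_me_gives_flat_curve(self):
        ranks = np.repeat(np.arange(1, 9), 3)
        me, meta = self._me(np.full(24, 0.2), ranks)
        fitted = fit_trajectory(me, meta, "M1")
        np.testing.assert_allclose(fitted.to_numpy(), 0.2, atol=1e-12)

    def test_linear_trend_span_one_matches_ols(self):
        ranks = np.repeat(np.arange(1, 9), 2)
        y = 0.5 * ranks - 1.0
        me, meta = self._me(y, ranks)
        fitted = fit_trajectory(me, meta, "M1", span=1.0)
        expected = 0.5 * np.arange(1, 9) - 1.0
        rng_y = y.max() - y.min()
        assert np.abs(fitted.to_numpy() - expected).max() < 0.05 * rng_y

    def test_few_periods_fall_back_to_means(self):
        ranks = np.array([1, 1, 2, 2, 3, 3])
        me, meta = self._me(np.array([1, 3, 5, 7, 9, 11.0]), ranks)
        fitted = fit_trajectory(me, meta, "M1")
        np.testing.assert_allclose(fitted.to_numpy(), [2, 6, 10])

    def test_planted_prenatal_module_peaks_prenatally(self, dev_tiny,
                                                      tiny_spec):
        dataset, truth = dev_tiny
        logged, _ = filter_genes(dataset)
        m = tiny_spec.ocd_module  # prenatal-peaking by design
        genes = [g for g in logged.genes if truth.module_of[g] == f"mod{m}"]
        labels = pd.Series(UNASSIGNED, index=logged.genes, dtype=object)
        labels[genes] = "M1"
        me = module_eigengenes(logged,
                               coexnet.ModulePartition(labels=labels))
        fitted = fit_trajectory(me, logged.metadata, "M1")
        assert fitted.idxmax() <= 4
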