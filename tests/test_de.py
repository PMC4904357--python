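import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from parturitrack import counts as counts_mod
from parturitrack import de
from parturitrack.counts import CountMatrix, NormFactors


def unit_norm_factors(cm):
    return NormFactors(pd.Series(1.0, index=cm.sample_ids), cm.lib_sizes)


def brute_force_exact_p(s_a, s_b, n_a, n_b, phi):
    """Exhaustive conditional summation over every split of the total,
    using a direct NB pmf expression (no log-sum-exp machinery)."""
    t = s_a + s_b

    def nb_pmf(k, n, mu):
        if phi < 1e-8:
            m = n * mu
            return np.exp(-m + k * np.log(m) - gammaln(k + 1)) if m > 0 else float(k == 0)
        r = n / phi
        m = n * mu
        return np.exp(gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                      + r * np.log(r / (r + m)) + k * np.log(m / (r + m)))

    mu = t / (n_a + n_b)
    probs = np.array([nb_pmf(a, n_a, mu) * nb_pmf(t - a, n_b, mu)
                      for a in range(t + 1)])
    obs = probs[s_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-9)].sum() / probs.sum())


def _cm_from_counts(vals, groups):
    counts = pd.DataFrame(np.asarray(vals),
                          index=[f"g{i}" for i in range(np.shape(vals)[0])],
                          columns=[f"s{i}" for i in range(np.shape(vals)[1])])
    sheet = pd.DataFrame({"group": groups},
                         index=pd.Index(counts.columns, name="sample_id"))
    return CountMatrix(counts, sheet)


class TestDispersion:
    def test_poisson_counts_give_near_zero_common(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(4, 1, size=2000)
        vals = rng.poisson(mu[:, None], size=(2000, 8))
        cm = _cm_from_counts(vals, ["A"] * 4 + ["B"] * 4)
        est = de.estimate_dispersion(cm, cm.samples["group"])
        assert est.common < 0.01

    def test_nb_dispersion_recovery(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(4.5, 0.8, size=1000)
            lam = rng.gamma(shape=10.0, scale=mu[:, None] / 10.0, size=(1000, 8))
            vals = rng.poisson(lam)
            cm = _cm_from_counts(vals, ["A"] * 4 + ["B"] * 4)
            est = de.estimate_dispersion(cm, cm.samples["group"])
            hits += 0.05 <= est.common <= 0.2
        assert hits == 20

    def test_constant_genes_zero_dispersion(self):
        vals = np.tile(np.array([[7], [30], [100]]), (1, 6))
        cm = _cm_from_counts(vals, ["A"] * 3 + ["B"] * 3)
        est = de.estimate_dispersion(cm, cm.samples["group"])
        assert est.common == 0.0

    def test_singleton_group_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(10, 100, size=(50, 5))
        cm = _cm_from_counts(vals, ["A"] * 2 + ["B"] * 2 + ["C"])
        with pytest.warns(UserWarning, match="1 sample"):
            de.estimate_dispersion(cm, cm.samples["group"])


class TestExactTest:
    def test_symmetric_null_gives_p_one(self):
        vals = np.tile(np.array([[12], [55], [200]]), (1, 4))
        cm = _cm_from_counts(vals, ["A", "A", "B", "B"])
        disp = de.DispersionEstimate(0.1, pd.Series(0.1, index=cm.gene_ids))
        res = de.exact_test(cm, unit_norm_factors(cm), disp, "A", "B")
        assert np.allclose(res.table["pvalue"], 1.0)
        assert np.allclose(res.table["logFC"], 0.0)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.1, 0.5])
    def test_matches_brute_force_enumeration(self, phi):
        # A = [2, 3] vs B = [10, 12]: small-total toy comparison
        p_impl = de.exact_test_pvalue(5, 22, 2, 2, phi)
        p_oracle = brute_force_exact_p(5, 22, 2, 2, phi)
        assert p_impl == pytest.approx(p_oracle, abs=1e-8)

    def test_batch_matches_scalar_on_random_totals(self):
        rng = np.random.default_rng(3)
        s_a = rng.integers(0, 30, size=40)
        s_b = rng.integers(0, 30, size=40)
        phi = rng.uniform(0.0, 0.6, size=40)
        batch = de._exact_pvalues_batch(s_a, s_b, 3, 4, phi)
        scalar = [de.exact_test_pvalue(a, b, 3, 4, f)
                  for a, b, f in zip(s_a, s_b, phi)]
        assert np.allclose(batch, scalar, atol=1e-10)

    def test_small_phi_converges_to_poisson_limit(self):
        p_small = de.exact_test_pvalue(8, 25, 2, 2, 1e-9)
        p_poisson = brute_force_exact_p(8, 25, 2, 2, 0.0)
        assert p_small == pytest.approx(p_poisson, rel=1e-6)

    def test_group_swap_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(8)
        vals = rng.integers(0, 300, size=(100, 6))
        cm = _cm_from_counts(vals, ["A"] * 3 + ["B"] * 3)
        disp = de.DispersionEstimate(0.1, pd.Series(0.1, index=cm.gene_ids))
        nf = unit_norm_factors(cm)
        ab = de.exact_test(cm, nf, disp, "A", "B")
        ba = de.exact_test(cm, nf, disp, "B", "A")
        assert np.allclose(ab.table["logFC"], -ba.table["logFC"], atol=1e-12)
        assert np.allclose(ab.table["pvalue"], ba.table["pvalue"], atol=1e-12)

    def test_empty_group_is_fatal(self, tiny_cm):
        disp = de.DispersionEstimate(0.1, pd.Series(0.1, index=tiny_cm.gene_ids))
        with pytest.raises(ValueError, match="empty group"):
            de.exact_test(tiny_cm, unit_norm_factors(tiny_cm), disp, "A", "Z")


class TestBH:
    def test_step_up_example(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert de.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adj = de.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestDegSetsAndOverlap:
    def _result(self, label, genes, logfc, fdr):
        table = pd.DataFrame({"logFC": logfc, "pvalue": fdr, "fdr": fdr}, index=genes)
        return de.ContrastResult(label, "x", table)

    def test_empty_when_nothing_significant(self):
        res = self._result("a", ["g1", "g2"], [1.0, -1.0], [0.5, 0.9])
        s = res.deg_set(0.001)
        assert s.up == set() and s.down == set()

    def test_partition_disjoint_and_identical(self):
        a = de.DEGSet("a", up={"g1"}, down={"g2"})
        b = de.DEGSet("b", up={"g3"}, down=set())
        part = de.overlap_partition([a, b])
        assert part["cells"]["a&b"] == 0
        assert part["cells"]["a"] == 2 and part["cells"]["b"] == 1
        same = de.overlap_partition([a, de.DEGSet("b", up={"g1"}, down={"g2"})])
        assert same["cells"]["a&b"] == 2
        assert same["cells"]["a"] == 0

    def test_venn_cells_sum_to_union(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        sets = []
        for label in ("t", "r", "l"):
            chosen = rng.choice(universe, size=20, replace=False)
            sets.append(de.DEGSet(label, up=set(chosen[:10]), down=set(chosen[10:])))
        part = de.overlap_partition(sets)
        assert sum(part["cells"].values()) == part["union_size"]

    def test_core_direction_split(self):
        sets = [de.DEGSet(m, up={"u1", "u2"}, down={"d1"}) for m in ("t", "r", "l")]
        sets[2] = de.DEGSet("l", up={"u1"}, down={"d1", "u2"})
        part = de.overlap_partition(sets)
        assert part["core_up"] == {"u1"}
        assert part["core_down"] == {"d1"}

    def test_model_union_handles_conflicting_directions(self):
        r1 = self._result("c1", ["g1", "g2"], [2.0, 2.0], [1e-5, 1e-5])
        r2 = self._result("c2", ["g1", "g2"], [-2.0, 2.0], [1e-5, 1e-5])
        union = de.model_deg_union([r1, r2], "m")
        assert "g1" not in union.up and "g1" not in union.down
        assert "g2" in union.up
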