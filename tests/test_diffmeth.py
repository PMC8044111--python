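"""Beta-binomial arcsine Wald test, dispersion shrinkage, global comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from mitometh import (
    DMLConfig,
    SimConfig,
    call_dml,
    dml_test,
    dml_test_paired,
    estimate_dispersion,
    global_compare,
    simulate_cohort,
    smooth_proportions,
)


def _site_table(pos, n_meth, cov, strand="L"):
    pos = np.atleast_1d(pos)
    n_meth = np.broadcast_to(n_meth, pos.shape)
    cov = np.broadcast_to(cov, pos.shape)
    return pd.DataFrame(
        {
            "chrom": "chrM",
            "pos": pos,
            "molecule_strand": strand,
            "n_meth": n_meth,
            "coverage_called": cov,
            "beta": n_meth / cov,
        }
    )


class TestSmoothing:
    def test_isolated_site_unchanged(self):
        sites = _site_table(np.array([100]), 5, 10)
        out = smooth_proportions(sites, window=50, circular=False)
        assert out["beta_smooth"].item() == out["beta"].item()

    def test_constant_field_invariant(self):
        pos = np.arange(0, 1000, 37)
        sites = _site_table(pos, 3, 10)
        out = smooth_proportions(sites, window=200, circular=True,
                                 genome_length=1000)
        assert np.allclose(out["beta_smooth"], 0.3)

    def test_three_neighbor_weighted_mean(self):
        sites = _site_table(np.array([90, 100, 110]),
                            np.array([0, 3, 6]), np.array([10, 10, 10]))
        out = smooth_proportions(sites, window=60, circular=False)
        center = out.loc[out["pos"] == 100, "beta_smooth"].item()
        assert center == pytest.approx(0.3)

    def test_circular_wrap_reaches_across_origin(self):
        sites = _site_table(np.array([2, 998]), np.array([0, 10]),
                            np.array([10, 10]))
        out = smooth_proportions(sites, window=20, circular=True,
                                 genome_length=1000)
        assert np.allclose(out["beta_smooth"], 0.5)


class TestEstimateDispersion:
    def test_binomial_data_gives_near_zero(self, rng):
        n, reps, N = 400, 40, 2000
        X = rng.binomial(N, 0.3, size=(n, reps))
        phi, _ = estimate_dispersion(X, np.full((n, reps), N),
                                     shrinkage_weight=0.0)
        assert abs(np.mean(phi)) < 0.005

    def test_full_shrinkage_gives_cross_site_median(self, rng):
        X = rng.binomial(50, 0.3, size=(100, 6))
        N = np.full((100, 6), 50)
        phi, raw = estimate_dispersion(X, N, shrinkage_weight=1.0)
        med = np.median(raw[np.isfinite(raw)])
        assert np.allclose(phi, med)

    def test_recovery_of_true_dispersion(self, rng):
        true_phi, p0, N, reps = 0.1, 0.3, 100, 50
        conc = 1 / true_phi - 1
        p = rng.beta(p0 * conc, (1 - p0) * conc, size=(500, reps))
        X = rng.binomial(N, p)
        phi, raw = estimate_dispersion(X, np.full_like(X, N),
                                       shrinkage_weight=0.0)
        assert abs(np.nanmean(raw) - true_phi) <= 0.03

    def test_single_replicate_falls_back_with_warning(self):
        X = np.array([[3], [5]])
        N = np.array([[10], [10]])
        with pytest.warns(UserWarning):
            phi, _ = estimate_dispersion(X, N)
        assert np.allclose(phi, 0.0)


class TestDmlTest:
    def test_identical_groups_null_result(self):
        reps = [_site_table(np.arange(5) * 10, np.arange(5), 20) for _ in range(3)]
        res = dml_test(reps, [t.copy() for t in reps])
        assert np.allclose(res["diff"], 0.0)
        assert np.allclose(res["wald"], 0.0)
        assert np.allclose(res["p"], 1.0)
        assert not res["significant"].any()

    def test_single_site_matches_symbolic_oracle(self):
        # independent recomputation of the Wald chain for one site
        x1, n1 = np.array([12.0, 15.0]), np.array([40.0, 50.0])
        x2, n2 = np.array([4.0, 2.0]), np.array([40.0, 30.0])
        g1 = [_site_table(np.array([7]), int(x), int(n)) for x, n in zip(x1, n1)]
        g2 = [_site_table(np.array([7]), int(x), int(n)) for x, n in zip(x2, n2)]
        cfg = DMLConfig(shrinkage_weight=0.5)
        res = dml_test(g1, g2, cfg)

        def mom(xs, ns):
            ph = xs / ns
            pb = xs.sum() / ns.sum()
            s2 = ph.var(ddof=1)
            inv = (1 / ns).mean()
            return min(max((s2 - pb * (1 - pb) * inv) /
                           (pb * (1 - pb) * (1 - inv)), 0.0), 0.99)

        raw = (mom(x1, n1) + mom(x2, n2)) / 2  # equal df per group
        phi = 0.5 * raw + 0.5 * raw  # single site: median == raw
        def wmean(xs, ns):
            y = np.arcsin(2 * (xs + 0.5) / (ns + 1) - 1)
            v = (1 + (ns - 1) * phi) / ns
            return (y / v).sum() / (1 / v).sum(), 1 / (1 / v).sum()

        m1, var1 = wmean(x1, n1)
        m2, var2 = wmean(x2, n2)
        se = math.sqrt(var1 + var2)
        wald = (m1 - m2) / se
        from scipy.stats import norm
        assert res["wald"].item() == pytest.approx(wald, abs=1e-9)
        assert res["p"].item() == pytest.approx(2 * norm.sf(abs(wald)), abs=1e-9)
        assert res["mu1"].item() == pytest.approx((math.sin(m1) + 1) / 2, abs=1e-9)

    def test_wald_sign_matches_proportion_diff(self, rng):
        pos = np.arange(100) * 7
        g1 = [_site_table(pos, rng.binomial(30, 0.4, 100), 30) for _ in range(3)]
        g2 = [_site_table(pos, rng.binomial(30, 0.3, 100), 30) for _ in range(3)]
        res = dml_test(g1, g2)
        nz = res[(res["diff"] != 0) & (res["diff_y"] != 0)]
        assert (np.sign(nz["diff"]) == np.sign(nz["diff_y"])).all()

    def test_fdr_monotone_and_dominates_p(self, rng):
        pos = np.arange(200) * 3
        g1 = [_site_table(pos, rng.binomial(25, 0.3, 200), 25) for _ in range(3)]
        g2 = [_site_table(pos, rng.binomial(25, 0.3, 200), 25) for _ in range(3)]
        res = dml_test(g1, g2).sort_values("p")
        assert (res["fdr"] >= res["p"] - 1e-12).all()
        assert (np.diff(res["fdr"]) >= -1e-12).all()

    def test_sites_missing_from_one_group_are_skipped(self):
        g1 = [_site_table(np.array([0, 10, 20]), 5, 20)]
        g1.append(_site_table(np.array([0, 10, 20]), 6, 20))
        g2 = [_site_table(np.array([0, 10]), 5, 20) for _ in range(2)]
        res = dml_test(g1, g2)
        assert set(res["pos"]) == {0, 10}


class TestCallDml:
    def test_delta_gate(self):
        res = pd.DataFrame({"diff": [0.04], "p": [1e-6], "fdr": [1e-5]})
        assert not call_dml(res, delta=0.05, p_threshold=0.05).item()

    def test_p_gate(self):
        res = pd.DataFrame({"diff": [0.10], "p": [0.20], "fdr": [0.3]})
        assert not call_dml(res, delta=0.05, p_threshold=0.05).item()

    def test_matches_boolean_oracle_on_random_tables(self, rng):
        res = pd.DataFrame(
            {
                "diff": rng.uniform(-0.3, 0.3, 500),
                "p": rng.uniform(0, 1, 500),
            }
        )
        res["fdr"] = np.minimum(res["p"] * 2, 1.0)
        for use_fdr in (False, True):
            got = call_dml(res, delta=0.05, p_threshold=0.05, use_fdr=use_fdr)
            col = "fdr" if use_fdr else "p"
            expected = [
                abs(d) >= 0.05 and v < 0.05
                for d, v in zip(res["diff"], res[col])
            ]
            assert list(got) == expected


class TestPairedTest:
    def _pairs(self, rng, n_pairs=6, n_sites=30, delta=0.0, phi_between=0.1):
        pos = np.arange(n_sites) * 11
        samples, _ = simulate_cohort(
            SimConfig(seed=int(rng.integers(0, 2**31))), n_pairs=n_pairs,
            effect_sites=pos[:3] if delta else [], delta_true=delta,
            coverage=100, positions=pos, phi_between=phi_between,
            phi_within=0.02)
        return [(samples[f"P{j}_T"], samples[f"P{j}_N"]) for j in range(n_pairs)]

    def test_identical_pairs_give_null(self):
        base = _site_table(np.arange(4) * 5, np.array([2, 4, 6, 8]), 20)
        pairs = [(base.copy(), base.copy()) for _ in range(3)]
        res = dml_test_paired(pairs)
        assert np.allclose(res["wald"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_single_pair_design_still_full_rank(self):
        base = _site_table(np.arange(4) * 5, np.array([2, 4, 6, 8]), 20)
        shifted = base.copy()
        shifted["n_meth"] += 5
        shifted["beta"] = shifted["n_meth"] / shifted["coverage_called"]
        with pytest.warns(UserWarning):
            res = dml_test_paired([(shifted, base)])
        assert np.isfinite(res["wald"]).all()
        assert len(res) == 4

    def test_paired_beats_unpaired_under_patient_effects(self, rng):
        ps_paired, ps_two = [], []
        for _ in range(10):
            pairs = self._pairs(rng, delta=0.15, phi_between=0.15)
            res_p = dml_test_paired(pairs)
            res_t = dml_test([p[0] for p in pairs], [p[1] for p in pairs])
            eff = res_p["pos"] < 33
            ps_paired.append(res_p.loc[eff, "p"].mean())
            ps_two.append(res_t.loc[res_t["pos"] < 33, "p"].mean())
        assert np.mean(ps_paired) < np.mean(ps_two)

    def test_power_on_paired_shift(self, rng):
        hits, total = 0, 0
        for _ in range(10):
            pairs = self._pairs(rng, delta=0.2, phi_between=0.05)
            res = dml_test_paired(pairs, DMLConfig(use_fdr=True))
            eff = res[res["pos"] < 33]
            hits += int(eff["significant"].sum())
            total += len(eff)
        assert hits / total >= 0.9


class TestGlobalCompare:
    def test_identical_paired_vectors_unit_p(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        assert global_compare(a, a.copy(), paired=True) == (0.0, 1.0)

    def test_exact_mann_whitney_enumeration(self):
        stat, p = global_compare([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_exact_and_asymptotic_agree_moderately(self, rng):
        a = rng.uniform(0, 1, 20)
        b = rng.uniform(0, 1, 20) + 0.1
        from scipy.stats import mannwhitneyu

        exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        approx = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic", use_continuity=True).pvalue
        assert abs(exact - approx) < 0.02

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError, match=">= 3"):
            global_compare([1, 2], [3, 4])
        with pytest.raises(ValueError, match="informative"):
            global_compare([1, 2, 3, 4], [1, 2, 3, 5], paired=True)

    def test_shifted_distributions_detected(self, rng):
        a = rng.beta(2, 5, 100)
        b = rng.beta(5, 2, 100)
        _, p = global_compare(a, b)
        assert p < 1e-6
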