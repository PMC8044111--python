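"""Generator behavior: determinism, coverage wrap, control-mode structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mitometh import (
    EmissionModel,
    NumtDecoyConfig,
    ReadLengthModel,
    Reference,
    SimConfig,
    make_reference,
    simulate_calls,
    simulate_cohort,
    summarize_sites,
)


def gaussian_tail_fpr(mu, sigma, t):
    """Closed-form per-call FPR of the two-component emitter on unmethylated DNA."""
    num = norm.cdf(-(t + mu) / sigma)
    return num / (num + norm.cdf((mu - t) / sigma))


class TestMakeReference:
    def test_deterministic_for_seed(self):
        a = make_reference(200, seed=7)
        b = make_reference(200, seed=7)
        assert a.seq == b.seq
        assert make_reference(200, seed=8).seq != a.seq

    def test_hand_enumerated_contexts(self):
        # ACGACA: CpG cytosine at 1; the only other forward C (pos 4) is CpH (CA)
        ref = Reference("ACGACA", circular=False)
        assert list(ref.cpg_positions("+")) == [1]
        assert list(ref.cph_positions("+")) == [4]

    def test_gc_free_alphabet_has_no_cpg(self):
        ref = make_reference(500, seed=0, alphabet="AT")
        assert ref.cpg_positions("+").size == 0
        assert ref.cytosine_positions("+").size == 0

    def test_reverse_strand_cytosines_sit_on_forward_g(self):
        ref = make_reference(300, seed=2)
        pos = ref.cytosine_positions("-")
        assert all(ref.seq[p] == "G" for p in pos)


class TestSimulateCalls:
    def test_seed_determinism_byte_identical(self):
        cfg = SimConfig(genome_length=2000, n_reads=10, seed=42)
        calls_a, truth_a = simulate_calls(cfg, mode="tissue")
        calls_b, truth_b = simulate_calls(cfg, mode="tissue")
        pd.testing.assert_frame_equal(calls_a, calls_b)
        pd.testing.assert_frame_equal(truth_a.reads, truth_b.reads)

    def test_full_length_reads_cover_every_strand_site_once(self):
        cfg = SimConfig(genome_length=1500, n_reads=8, seed=5,
                        read_length_model=ReadLengthModel(full_length_fraction=1.0))
        calls, truth = simulate_calls(cfg, mode="tissue")
        per_read = calls.groupby(["read_name", "strand"]).size()
        for (read, strand), n in per_read.items():
            expected = truth.site_positions[strand].size
            assert n == expected
        # and each position exactly once per read
        dup = calls.groupby(["read_name", "start"]).size()
        assert (dup == 1).all()

    def test_degenerate_fu_emitter_never_calls_methylated(self):
        cfg = SimConfig(genome_length=1000, n_reads=5, seed=1,
                        emission=EmissionModel(mu=4.0, sigma=0.0))
        calls, _ = simulate_calls(cfg, mode="FU")
        assert np.allclose(calls["log_lik_ratio"], -4.0)
        sites = summarize_sites(calls, threshold=2.0)
        assert (sites["n_meth"] == 0).all()

    def test_forced_single_site_reaches_frequency_one(self):
        ref = make_reference(1200, seed=3)
        p = {s: np.zeros(ref.cytosine_positions(s).size) for s in "+-"}
        target = int(ref.cytosine_positions("+")[10])
        p["+"][10] = 1.0
        cfg = SimConfig(genome_length=1200, n_reads=200, seed=3,
                        site_meth_prob=p,
                        emission=EmissionModel(mu=4.0, sigma=0.1))
        calls, _ = simulate_calls(cfg, mode="tissue", reference=ref)
        sites = summarize_sites(calls, threshold=2.0)
        row = sites[(sites["pos"] == target) & (sites["molecule_strand"] == "L")]
        assert row["beta"].item() == 1.0

    def test_strand_fraction_recovered(self):
        cfg = SimConfig(genome_length=800, n_reads=600, seed=9,
                        strand_h_fraction=0.7)
        _, truth = simulate_calls(cfg, mode="FU")
        frac = (truth.reads["molecule_strand"] == "H").mean()
        se = np.sqrt(0.7 * 0.3 / 600)
        assert abs(frac - 0.7) <= 3 * se

    def test_fm_failure_fraction_recovered(self):
        # near-perfect emitter: every non-failure read has >=1 methylated call
        cfg = SimConfig(genome_length=2000, n_reads=400, seed=13,
                        fm_failure_fraction=0.2,
                        emission=EmissionModel(mu=10.0, sigma=0.5))
        calls, truth = simulate_calls(cfg, mode="FM")
        meth_per_read = (
            calls.assign(meth=calls["log_lik_ratio"] >= 2.0)
            .groupby("read_name")["meth"].sum()
        )
        frac_zero = (meth_per_read == 0).mean()
        se = np.sqrt(0.2 * 0.8 / 400)
        assert abs(frac_zero - 0.2) <= 3 * se
        # calls agree with the recorded truth
        failures = set(truth.reads.loc[truth.reads["fm_failure"], "read_id"])
        assert failures == set(meth_per_read.index[meth_per_read == 0])

    def test_fu_fpr_matches_gaussian_tail(self):
        cfg = SimConfig(genome_length=4000, n_reads=12, seed=21,
                        emission=EmissionModel(mu=4.0, sigma=2.5))
        calls, _ = simulate_calls(cfg, mode="FU")
        codes = np.where(calls["log_lik_ratio"] >= 2.0, 1,
                         np.where(calls["log_lik_ratio"] <= -2.0, -1, 0))
        called = codes != 0
        fpr_hat = (codes == 1).sum() / called.sum()
        expected = gaussian_tail_fpr(4.0, 2.5, 2.0)
        se = np.sqrt(expected * (1 - expected) / called.sum())
        assert abs(fpr_hat - expected) <= 3 * se

    def test_numt_decoys_are_short_and_labeled(self):
        cfg = SimConfig(genome_length=16569, n_reads=5, seed=2,
                        numt_decoys=NumtDecoyConfig(count=20))
        _, truth = simulate_calls(cfg, mode="tissue")
        numts = truth.reads[truth.reads["is_numt"]]
        assert len(numts) == 20
        assert (numts["length"] <= 8798).all()
        assert (numts["start"] + numts["length"] <= 16569).all()

    def test_zero_covered_sites_warns_and_returns_empty(self):
        cfg = SimConfig(genome_length=300, n_reads=3, seed=0)
        ref = make_reference(300, seed=0, alphabet="AT")
        with pytest.warns(UserWarning, match="no cytosine"):
            calls, _ = simulate_calls(cfg, mode="FU", reference=ref)
        assert len(calls) == 0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="strand_h_fraction"):
            SimConfig(strand_h_fraction=1.5)
        with pytest.raises(ValueError, match="length_bp"):
            SimConfig(genome_length=1000,
                      numt_decoys=NumtDecoyConfig(count=1, length_bp=2000))


class TestSimulateCohort:
    def test_null_groups_are_exchangeable(self):
        pos = np.arange(200) * 10
        samples, truth = simulate_cohort(
            SimConfig(seed=1), n_pairs=4, effect_sites=[], delta_true=0.0,
            coverage=60, positions=pos)
        assert not truth["is_effect"].any()
        t_mean = np.mean([samples[f"P{j}_T"]["beta"].mean() for j in range(4)])
        n_mean = np.mean([samples[f"P{j}_N"]["beta"].mean() for j in range(4)])
        assert abs(t_mean - n_mean) < 0.02

    def test_effect_sites_have_largest_observed_differences(self):
        pos = np.arange(100) * 10
        effect = pos[:10]
        diffs = np.zeros(100)
        for seed in range(20):
            samples, _ = simulate_cohort(
                SimConfig(seed=seed), n_pairs=6, effect_sites=effect,
                delta_true=0.2, coverage=100, positions=pos)
            t = np.mean([samples[f"P{j}_T"]["beta"].to_numpy() for j in range(6)], axis=0)
            n = np.mean([samples[f"P{j}_N"]["beta"].to_numpy() for j in range(6)], axis=0)
            diffs += t - n
        top10 = set(pos[np.argsort(-np.abs(diffs))[:10]])
        assert top10 == set(effect)

    def test_effect_sites_must_be_simulated_positions(self):
        with pytest.raises(ValueError, match="subset"):
            simulate_cohort(SimConfig(seed=0), n_pairs=2, effect_sites=[7],
                            delta_true=0.1, positions=np.array([0, 10]))

    def test_delta_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            simulate_cohort(SimConfig(seed=0), n_pairs=2, effect_sites=[0],
                            delta_true=0.5, positions=np.array([0, 10]),
                            base_meth=0.7, phi_between=0.0, phi_within=0.0)
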