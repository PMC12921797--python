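import numpy as np
import pytest
from scipy.stats import spearmanr

from ddnet.connectivity import wpli_epochs
from ddnet.graphs import weighted_clustering
from ddnet.montage import CHANNELS_40
from ddnet.preprocess import CANONICAL_BANDS, EpochSet
from ddnet.synth import (BehavioralRecord, GroundTruthNetwork,
                         default_cohort_truth, inject_artifacts,
                         make_ground_truth_network,
                         make_paired_ground_truth_networks,
                         simulate_band_epochs, simulate_behavior,
                         simulate_cohort_epochs)

THETA = CANONICAL_BANDS[1]


class TestGroundTruthNetwork:
    def test_pure_ring_lattice_clustering(self):
        """k=4 ring lattice has unweighted clustering 3(k−2)/(4(k−1))."""
        net = make_ground_truth_network(20, 4, 0.0, seed=7)
        topo = (net.adjacency > 0).astype(float)
        _, c = weighted_clustering(topo)
        assert c == pytest.approx(0.5)

    def test_full_rewiring_approaches_random_expectation(self):
        """At p=1 mean clustering tends to the Erdős–Rényi value k/n."""
        cs = []
        for seed in range(200):
            net = make_ground_truth_network(20, 4, 1.0, seed=seed)
            topo = (net.adjacency > 0).astype(float)
            cs.append(weighted_clustering(topo)[1])
        assert np.mean(cs) == pytest.approx(4 / 20, abs=0.05)

    def test_clustering_decreases_with_rewiring(self):
        lo = make_ground_truth_network(20, 4, 0.05, seed=7)
        hi = make_ground_truth_network(20, 4, 0.6, seed=7)
        c_lo = weighted_clustering((lo.adjacency > 0).astype(float))[1]
        c_hi = weighted_clustering((hi.adjacency > 0).astype(float))[1]
        assert c_lo > c_hi

    def test_invariants(self):
        net = make_ground_truth_network(16, 4, 0.3, seed=1)
        assert np.allclose(net.adjacency, net.adjacency.T)
        assert np.allclose(net.lag, -net.lag.T)
        assert (net.adjacency >= 0).all()
        lags = np.abs(net.lag[net.adjacency > 0])
        assert (lags >= np.pi / 8 - 1e-12).all()
        assert (lags <= 3 * np.pi / 8 + 1e-12).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="even k"):
            make_ground_truth_network(10, 3, 0.1)
        with pytest.raises(ValueError, match="even k"):
            make_ground_truth_network(4, 6, 0.1)
        with pytest.raises(ValueError, match="rewiring_p"):
            make_ground_truth_network(10, 4, 1.5)

    def test_reproducible_under_seed(self):
        a = make_ground_truth_network(12, 4, 0.2, seed=42)
        b = make_ground_truth_network(12, 4, 0.2, seed=42)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.lag, b.lag)


class TestPairedNetworks:
    def test_marginals_and_nesting(self):
        nets = make_paired_ground_truth_networks(
            24, 6, {"control": 0.1, "dd": 0.5}, seed=3)
        ring = make_paired_ground_truth_networks(
            24, 6, {"ring": 0.0}, seed=3)["ring"]
        off_c = ((nets["control"].adjacency > 0) != (ring.adjacency > 0)).sum()
        off_d = ((nets["dd"].adjacency > 0) != (ring.adjacency > 0)).sum()
        assert off_d > off_c  # the higher-p group deviates more
        c_ctrl = weighted_clustering(
            (nets["control"].adjacency > 0).astype(float))[1]
        c_dd = weighted_clustering((nets["dd"].adjacency > 0).astype(float))[1]
        assert c_ctrl > c_dd

    def test_common_base_weights(self):
        nets = make_paired_ground_truth_networks(
            20, 4, {"a": 0.0, "b": 0.0}, seed=9)
        assert np.array_equal(nets["a"].adjacency, nets["b"].adjacency)
        assert np.array_equal(nets["a"].lag, nets["b"].lag)


def _two_channel_network(lag=np.pi / 2, weight=1.0):
    adj = np.array([[0.0, weight], [weight, 0.0]])
    lags = np.array([[0.0, lag], [-lag, 0.0]])
    return GroundTruthNetwork(n_nodes=2, adjacency=adj, lag=lags)


class TestSimulateBandEpochs:
    def test_single_edge_quarter_lag_recovers_high_wpli(self):
        """A lone strongly coupled pair without jitter approaches wPLI 1."""
        net = _two_channel_network()
        data = simulate_band_epochs(net, THETA, n_trials=60, n_samples=200,
                                    seed=0, jitter_sd_scale=0.0)
        es = EpochSet(data=data, fs=250.0)
        m = wpli_epochs(es, mode="trials")[0]
        assert m.values[0, 1] > 0.9

    def test_zero_coupling_network_stays_at_noise_floor(self):
        """Uncoupled narrowband channels sit at the estimator's sampling
        floor: mean near zero and every pair within the Monte-Carlo null
        of the debiased across-trial estimator at this sample size."""
        def one_net(seed):
            net = GroundTruthNetwork(n_nodes=6, adjacency=np.zeros((6, 6)),
                                     lag=np.zeros((6, 6)))
            data = simulate_band_epochs(net, THETA, n_trials=30,
                                        n_samples=200, seed=seed)
            m = wpli_epochs(EpochSet(data=data, fs=250.0), mode="trials",
                            debias=True)[0]
            return m.values[np.triu_indices(6, 1)]
        null = np.concatenate([one_net(100 + s) for s in range(12)])
        probe = one_net(1)
        assert probe.mean() < 0.15
        assert probe.max() <= null.max() + 0.1

    def test_wpli_monotone_in_coupling_strength(self):
        """Rank correlation with planted weights must exceed 0.8.

        Disjoint coupled pairs probe the estimator's steep regime (an
        anchor edge at the maximum weight absorbs the normalisation, so
        the probes stay below the saturation point of the bounded
        estimator)."""
        n = 18  # 8 probe pairs plus one anchor pair
        weights = np.concatenate([np.linspace(0.05, 0.55, 8), [1.0]])
        adj = np.zeros((n, n))
        lags = np.zeros((n, n))
        for e, w in enumerate(weights):
            i, j = 2 * e, 2 * e + 1
            adj[i, j] = adj[j, i] = w
            lags[i, j], lags[j, i] = np.pi / 4, -np.pi / 4
        net = GroundTruthNetwork(n_nodes=n, adjacency=adj, lag=lags)
        rhos = []
        for seed in range(5):
            data = simulate_band_epochs(net, THETA, n_trials=30,
                                        n_samples=200, seed=seed)
            m = wpli_epochs(EpochSet(data=data, fs=250.0), mode="trials",
                            debias=True)[0]
            est = [m.values[2 * e, 2 * e + 1] for e in range(8)]
            rhos.append(spearmanr(weights[:8], est).statistic)
        assert np.mean(rhos) > 0.8

    def test_artifact_injection_rate(self, rng):
        data = np.zeros((50, 4, 200))
        out = inject_artifacts(data, artifact_rate=0.2, rng=rng)
        n_hit = (np.abs(out) > 200).any(axis=(1, 2)).sum()
        # binomial(50, 0.2): central 99 % interval ≈ [3, 18]
        assert 3 <= n_hit <= 18


class TestSimulateCohort:
    def test_shapes_labels_and_determinism(self):
        truth = default_cohort_truth(
            seed=5, bands=(THETA,), montage_labels=CHANNELS_40[:8],
            n_subjects={"control": 2, "dd": 2},
            epochs_per_subject={"control": (10, 0), "dd": (10, 0)})
        e1 = simulate_cohort_epochs(truth)
        e2 = simulate_cohort_epochs(truth)
        es = e1["control"]["control00"]["word"]
        assert es.data.shape == (10, 8, 200)
        assert es.channels == tuple(CHANNELS_40[:8])
        assert es.group == "control" and es.condition == "word"
        # bit-identical regeneration from the same truth
        assert np.array_equal(
            es.data, e2["control"]["control00"]["word"].data)

    def test_clean_amplitudes_within_plausible_scalp_range(self):
        truth = default_cohort_truth(
            seed=5, bands=(THETA,), montage_labels=CHANNELS_40[:8],
            n_subjects={"control": 1, "dd": 1},
            epochs_per_subject={"control": (10, 0), "dd": (10, 0)},
            artifact_rate=0.0)
        es = simulate_cohort_epochs(truth)["control"]["control00"]["word"]
        peak = np.abs(es.data).max()
        assert 30 < peak < 200  # clean data clears the ±200 µV rule

    def test_empty_band_list_rejected(self):
        truth = default_cohort_truth(
            seed=5, bands=(THETA,), montage_labels=CHANNELS_40[:8],
            n_subjects={"control": 1, "dd": 1})
        truth.bands = ()
        with pytest.raises(ValueError, match="band list"):
            simulate_cohort_epochs(truth)

    def test_truth_records_planted_contrast(self):
        truth = default_cohort_truth(
            seed=5, bands=(THETA,), montage_labels=CHANNELS_40[:12],
            n_subjects={"control": 1, "dd": 1})
        pc = truth.planted_clustering
        assert pc["control"]["rewiring_p"] == 0.1
        assert pc["dd"]["rewiring_p"] == 0.5
        assert pc["control"]["mean_truth_clustering"] > \
            pc["dd"]["mean_truth_clustering"]


class TestSimulateBehavior:
    PARAMS = {"base_ies_ms": 2000.0, "slope_ies_vs_phi": -2000.0,
              "rt_noise_sd_ms": 100.0,
              "accuracy_logit_params": {"a0": 1.0, "a1": 0.0}}

    def test_perfect_accuracy_makes_ies_equal_mean_rt(self):
        params = dict(self.PARAMS, rt_noise_sd_ms=0.0,
                      accuracy_logit_params={"a0": 50.0, "a1": 0.0})
        recs = simulate_behavior({"s0": 0.5}, params, n_trials=20, seed=0)
        assert all(r.correct for r in recs)
        rts = [r.rt_ms for r in recs]
        assert np.mean(rts) == pytest.approx(2000 - 2000 * 0.5, rel=1e-6)

    def test_null_slope_recovered_as_null(self, rng):
        from ddnet.stats import compute_ies, robust_regress
        params = dict(self.PARAMS, slope_ies_vs_phi=0.0, rt_noise_sd_ms=0.5,
                      accuracy_logit_params={"a0": 50.0, "a1": 0.0})
        phis = {f"s{i}": p for i, p in enumerate(rng.uniform(0.2, 0.8, 20))}
        recs = simulate_behavior(phis, params, n_trials=60, seed=1)
        ies = compute_ies(recs)
        fit = robust_regress(ies.ies_ms, [phis[s] for s in ies.subject_id])
        assert abs(fit.slope) < 50  # ≈ 0 against a 2000 ms baseline

    def test_invalid_accuracy_parameters_rejected(self):
        params = dict(self.PARAMS,
                      accuracy_logit_params={"a0": -60.0, "a1": 0.0})
        with pytest.raises(ValueError, match="nonpositive IES|p outside"):
            # p ≈ 0 forces mean RT toward 0, caught by validation
            simulate_behavior({"s0": 1.0}, dict(params, base_ies_ms=1.0),
                              n_trials=5, seed=0)

    def test_rt_positive_invariant(self):
        recs = simulate_behavior({"s0": 0.9}, self.PARAMS, n_trials=200,
                                 seed=3)
        assert all(r.rt_ms > 0 for r in recs)
        with pytest.raises(ValueError, match="positive"):
            BehavioralRecord("s", "g", "word", rt_ms=-5.0, correct=True)
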