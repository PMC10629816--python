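"""Smoothing, binarization, Baum-Welch, Viterbi and burst statistics."""

import itertools

import numpy as np
import pytest

from snaburst.hmm import (
    BurstStateHMM,
    HmmParams,
    aggregate_kinetics,
    baum_welch_fit,
    binarize_by_slope,
    burst_kinetics,
    loess_smooth,
    viterbi_decode,
)
from snaburst.simulate import EmbryoConfig, KineticField, generate_embryo, simulate_promoter_path


class TestLoess:
    def test_constant_unchanged(self):
        y = np.full(50, 7.0)
        np.testing.assert_allclose(loess_smooth(y), y, atol=1e-10)

    def test_linear_unchanged(self):
        """Local linear regression reproduces straight lines."""
        y = 2.0 * np.arange(60) + 5.0
        np.testing.assert_allclose(loess_smooth(y, span=0.3), y, atol=1e-8)

    def test_noise_reduction_on_sine(self, rng):
        t = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.3, t.size)
        smooth = loess_smooth(noisy, t, span=0.1)
        assert np.sqrt(np.mean((smooth - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.zeros(3))


class TestBinarize:
    def test_increasing_all_ones(self):
        assert binarize_by_slope(np.arange(10.0)).all()

    def test_decreasing_all_zeros(self):
        assert not binarize_by_slope(np.arange(10.0)[::-1]).any()

    def test_triangle_wave_blocks_match_difference_signs(self):
        p = 5
        y = np.concatenate([np.r_[np.arange(p), p - np.arange(p)] for _ in range(4)]).astype(float)
        b = binarize_by_slope(y)
        d = np.diff(y)
        prev = 0
        expected = []
        for v in d:
            prev = 1 if v > 0 else (0 if v < 0 else prev)
            expected.append(prev)
        np.testing.assert_array_equal(b, expected)

    def test_tie_carries_previous(self):
        b = binarize_by_slope(np.array([0.0, 0.0, 1.0, 1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(b, [0, 1, 1, 0, 0])


class TestBaumWelch:
    def test_clean_blocks_give_persistent_states(self):
        seq = np.tile(np.r_[np.ones(100, int), np.zeros(100, int)], 3)
        params = baum_welch_fit(seq)
        assert params.transmat[0, 0] >= 0.98
        assert params.transmat[1, 1] >= 0.98
        assert params.converged

    def test_all_ones_degenerate(self):
        params = baum_welch_fit(np.ones(50, dtype=int))
        assert params.degenerate
        assert params.transmat[1, 1] == pytest.approx(1.0)

    def test_recovery_from_known_hmm(self, rng):
        """Pooled transition estimates land within 0.05 of the generating
        matrix for 50 sequences of 150 frames."""
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        p1 = np.array([0.15, 0.85])
        seqs = []
        for _ in range(50):
            s = np.empty(150, dtype=int)
            obs = np.empty(150, dtype=int)
            state = int(rng.random() < 0.5)
            for t in range(150):
                state = int(rng.random() < A[state, 1])
                s[t] = state
                obs[t] = int(rng.random() < p1[state])
            seqs.append(obs)
        params = baum_welch_fit(seqs)
        np.testing.assert_allclose(params.transmat, A, atol=0.05)

    def test_likelihood_matches_hmmlearn(self, rng):
        """Forward-pass likelihood agrees with an independent HMM
        implementation at identical, fixed parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        from snaburst.hmm import _forward_backward

        seq = (rng.random(80) < 0.4).astype(int)
        A = np.array([[0.85, 0.15], [0.3, 0.7]])
        p1 = np.array([0.25, 0.75])
        start = np.array([0.6, 0.4])
        B = np.vstack([1 - p1, p1]).T
        ll_ours, _, _ = _forward_backward(seq, A, B, start)
        m = hmmlearn.CategoricalHMM(n_components=2, init_params="")
        m.startprob_ = start
        m.transmat_ = A
        m.emissionprob_ = B
        ll_ref = m.score(seq.reshape(-1, 1))
        assert ll_ours == pytest.approx(ll_ref, abs=1e-9)


def enumerate_best_path(seq, params):
    """Exhaustive MAP path search (oracle)."""
    best, best_lp = None, -np.inf
    B = np.vstack([1 - params.emission_p1, params.emission_p1]).T
    for path in itertools.product((0, 1), repeat=len(seq)):
        lp = np.log(params.startprob[path[0]]) + np.log(B[path[0], seq[0]])
        for t in range(1, len(seq)):
            lp += np.log(params.transmat[path[t - 1], path[t]]) + np.log(B[path[t], seq[t]])
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


class TestViterbi:
    @pytest.fixture()
    def params(self):
        return HmmParams(
            transmat=np.array([[0.85, 0.15], [0.25, 0.75]]),
            emission_p1=np.array([0.2, 0.8]),
            startprob=np.array([0.6, 0.4]),
        )

    def test_near_deterministic_emissions_follow_observations(self):
        params = HmmParams(
            transmat=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emission_p1=np.array([0.001, 0.999]),
            startprob=np.array([0.5, 0.5]),
        )
        seq = np.r_[np.ones(10, int), np.zeros(10, int), np.ones(5, int)]
        path, _ = viterbi_decode(seq, params)
        np.testing.assert_array_equal(path, seq)

    def test_matches_exhaustive_enumeration(self, params, rng):
        """Viterbi log-probability equals the exhaustive maximum for random
        sequences up to length 8."""
        for L in range(2, 9):
            seq = (rng.random(L) < 0.5).astype(int)
            path, lp = viterbi_decode(seq, params)
            _, best_lp = enumerate_best_path(seq, params)
            assert lp == pytest.approx(best_lp, abs=1e-9)

    def test_beats_random_paths_and_observation_path(self, params, rng):
        def path_lp(path, seq):
            B = np.vstack([1 - params.emission_p1, params.emission_p1]).T
            lp = np.log(params.startprob[path[0]]) + np.log(B[path[0], seq[0]])
            for t in range(1, len(seq)):
                lp += np.log(params.transmat[path[t - 1], path[t]]) + np.log(B[path[t], seq[t]])
            return lp

        seq = (rng.random(40) < 0.5).astype(int)
        _, lp = viterbi_decode(seq, params)
        assert lp >= path_lp(seq, seq) - 1e-12
        for _ in range(100):
            rand = (rng.random(40) < 0.5).astype(int)
            assert lp >= path_lp(rand, seq) - 1e-12

    def test_deterministic_under_symmetric_params(self):
        params = HmmParams(
            transmat=np.full((2, 2), 0.5),
            emission_p1=np.array([0.5, 0.5]),
            startprob=np.array([0.5, 0.5]),
        )
        seq = np.array([0, 1, 0, 1])
        p1, _ = viterbi_decode(seq, params)
        p2, _ = viterbi_decode(seq, params)
        np.testing.assert_array_equal(p1, p2)  # tie rule -> OFF everywhere
        assert not p1.any()


class TestBurstKinetics:
    def test_single_interior_burst(self):
        """ON frames 10-19 of a long movie at 21 s: one 3.5 min burst,
        k_off = 1/3.5 = 0.286 min^-1."""
        path = np.zeros(100, dtype=int)
        path[10:20] = 1
        kin = burst_kinetics(path, 21.0)
        assert kin.n_bursts == 1
        assert kin.burst_durations[0] == pytest.approx(3.5)
        assert kin.k_off == pytest.approx(1 / 3.5, rel=1e-12)

    def test_all_off_flagged(self):
        kin = burst_kinetics(np.zeros(50, dtype=int), 21.0)
        assert kin.n_bursts == 0
        assert np.isnan(kin.k_on) and np.isnan(kin.k_off)

    def test_edge_runs_censored(self):
        path = np.r_[np.ones(5, int), np.zeros(5, int), np.ones(4, int), np.zeros(3, int)]
        kin = burst_kinetics(path, 60.0)
        assert kin.n_bursts == 1  # only the interior ON run
        assert kin.burst_durations[0] == pytest.approx(4.0)

    def test_sampled_chain_closed_form(self):
        """Run-length rate estimates on point-sampled telegraph paths match
        the sampled-chain closed form: mean run length = dt/(1 - p_stay)
        with p_stay from the matrix exponential of the generator."""
        kon, koff, dt_s = 1.0, 2.0, 21.0
        dt = dt_s / 60.0
        lam = kon + koff
        E = np.exp(-lam * dt)
        p_on_on = (kon + koff * E) / lam
        p_off_off = (koff + kon * E) / lam
        durs, seps = [], []
        rng_seed = 0
        for n in range(300):
            path = simulate_promoter_path(kon, koff, 60.0, dt_s, rng=rng_seed + n)
            kin = burst_kinetics(path, dt_s)
            durs.extend(kin.burst_durations)
            seps.extend(kin.burst_separations)
        assert np.mean(durs) == pytest.approx(dt / (1 - p_on_on), rel=0.05)
        assert np.mean(seps) == pytest.approx(dt / (1 - p_off_off), rel=0.05)

    def test_recovery_at_default_rates(self):
        """At the generator's default rates (kon=0.5, koff=0.25 min^-1) the
        pooled run-length estimates on true paths are within 15% of truth
        (the discretization bias at 21 s frames is ~10%, simulation oracle)."""
        kon, koff = 0.5, 0.25
        durs, seps = [], []
        for n in range(200):
            path = simulate_promoter_path(kon, koff, 60.0, 21.0, rng=1000 + n)
            kin = burst_kinetics(path, 21.0)
            durs.extend(kin.burst_durations)
            seps.extend(kin.burst_separations)
        assert 1 / np.mean(durs) == pytest.approx(koff, rel=0.15)
        assert 1 / np.mean(seps) == pytest.approx(kon, rel=0.15)


class TestFullChain:
    def test_monotone_response_to_koff(self):
        """Raising the generating koff raises the pooled recovered k_off and
        lowers the mean burst duration across a 3-point ladder.  The ladder
        keeps mean burst durations at or below the signal dwell time, the
        regime where the slope of the fluorescence signal still tracks
        switching (longer bursts plateau and their slope carries no state
        information)."""
        recovered, durations = [], []
        for i, koff in enumerate((0.5, 1.0, 2.0)):
            field = KineticField(kon=0.5, koff=koff, loading_rate=200.0, noise_sd=20.0)
            traces = generate_embryo(
                EmbryoConfig(n_nuclei=40, duration=50.0, seed=600 + i), field
            )
            hmm = BurstStateHMM()
            durs = []
            for tr in traces:
                kin = hmm.decode(tr)
                if kin is not None:
                    durs.extend(kin.burst_durations)
            durations.append(np.mean(durs))
            recovered.append(1.0 / np.mean(durs))
        assert recovered[0] < recovered[1] < recovered[2]
        assert durations[0] > durations[1] > durations[2]

    def test_stationary_consistency_of_decoded_paths(self, small_embryo):
        """Decoded ON fraction agrees with kon/(kon+koff) computed from the
        recovered rates (within 10%)."""
        hmm = BurstStateHMM()
        on_frac, durs, seps = [], [], []
        for tr in small_embryo:
            kin = hmm.decode(tr)
            if kin is None or not kin.burst_separations.size or not kin.n_bursts:
                continue
            on_frac.append(kin.path.mean())
            durs.extend(kin.burst_durations)
            seps.extend(kin.burst_separations)
        k_off = 1 / np.mean(durs)
        k_on = 1 / np.mean(seps)
        assert np.mean(on_frac) == pytest.approx(k_on / (k_on + k_off), rel=0.10)


class TestAggregate:
    def test_single_nucleus_group(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "genotype": ["WT"],
                "k_on_permin": [0.5],
                "k_off_permin": [0.3],
                "mean_duration_min": [3.0],
                "mean_separation_min": [2.0],
            }
        )
        out = aggregate_kinetics(df)
        assert out.loc["WT", "k_on_permin_mean"] == 0.5
        assert out.loc["WT", "k_on_permin_count"] == 1

    def test_koff_doubling_recovered_from_truth_paths(self):
        """Two simulated groups with equal kon and koff differing 2x:
        group k_off means differ by a factor in [1.6, 2.4] and k_on means
        agree within 15% (kinetics measured on the truth paths)."""
        import pandas as pd

        rows = []
        for geno, koff, seed in (("A", 0.25, 0), ("B", 0.5, 1)):
            for n in range(150):
                path = simulate_promoter_path(0.5, koff, 60.0, 21.0, rng=seed * 10_000 + n)
                kin = burst_kinetics(path, 21.0)
                if kin.n_bursts and kin.burst_separations.size:
                    rows.append(
                        {
                            "genotype": geno,
                            "k_on_permin": kin.k_on,
                            "k_off_permin": kin.k_off,
                            "mean_duration_min": kin.burst_durations.mean(),
                            "mean_separation_min": kin.burst_separations.mean(),
                        }
                    )
        df = pd.DataFrame(rows)
        out = aggregate_kinetics(df)
        ratio = out.loc["B", "k_off_permin_mean"] / out.loc["A", "k_off_permin_mean"]
        assert 1.6 <= ratio <= 2.4
        kon_a, kon_b = out.loc["A", "k_on_permin_mean"], out.loc["B", "k_on_permin_mean"]
        assert abs(kon_a - kon_b) / kon_a < 0.15

    def test_shuffled_labels_consistent_with_null(self, rng):
        """Permuting genotype labels destroys the group difference."""
        import pandas as pd

        from snaburst.features import compare_groups

        rows = []
        for geno, koff, seed in (("A", 0.25, 5), ("B", 0.5, 6)):
            for n in range(80):
                path = simulate_promoter_path(0.5, koff, 60.0, 21.0, rng=seed * 10_000 + n)
                kin = burst_kinetics(path, 21.0)
                if kin.n_bursts:
                    rows.append({"genotype": geno, "k_off": kin.k_off})
        df = pd.DataFrame(rows)
        t_obs, p_obs = compare_groups(
            df.loc[df.genotype == "A", "k_off"], df.loc[df.genotype == "B", "k_off"]
        )
        assert p_obs < 0.01
        labels = df["genotype"].to_numpy().copy()
        null_ts = []
        for _ in range(200):
            rng.shuffle(labels)
            t_null, _ = compare_groups(df.loc[labels == "A", "k_off"], df.loc[labels == "B", "k_off"])
            null_ts.append(abs(t_null))
        assert np.mean(np.array(null_ts) >= abs(t_obs)) < 0.05
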