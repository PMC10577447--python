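"""Inference: Wilcoxon, cluster permutation, participant permutation, summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rfttag.spectral import (
    BASELINE_WINDOW_S,
    STIM_WINDOW_S,
    TrialCoefficients,
    trial_coefficients,
)
from rfttag.stats import (
    DegenerateTestError,
    cluster_permutation_test,
    fit_condition_slope,
    lateralization_index,
    participant_permutation_test,
    proportion_significant,
    wilcoxon_signed_rank,
)


class TestWilcoxon:
    def test_exact_p_for_five_concordant_pairs(self):
        # oracle: enumerate all 2^5 sign assignments of ranks 1..5
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.zeros(5)
        res = wilcoxon_signed_rank(a, b)
        w_plus = [sum(r for r, s in zip(range(1, 6), signs) if s > 0)
                  for signs in itertools.product((1, -1), repeat=5)]
        observed = 15.0                              # all ranks positive
        more_extreme = np.mean([min(w, 15 - w) <= min(observed, 15 - observed)
                                for w in w_plus])
        assert res.p_value == pytest.approx(0.0625)
        assert res.p_value == pytest.approx(more_extreme)
        assert res.method == "exact"
        assert res.z_value > 0

    def test_swapping_inputs_negates_z(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=12), rng.normal(size=12)
        fwd = wilcoxon_signed_rank(a, b)
        rev = wilcoxon_signed_rank(b, a)
        assert fwd.z_value == pytest.approx(-rev.z_value)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_identical_vectors_flagged_degenerate(self):
        x = np.arange(6.0)
        with pytest.raises(DegenerateTestError, match="zero"):
            wilcoxon_signed_rank(x, x)

    def test_too_few_nonzero_pairs_rejected(self):
        a = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(DegenerateTestError, match="at least 5"):
            wilcoxon_signed_rank(a, b)

    def test_z_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0.3, 1.0, size=30)
        b = rng.normal(0.0, 1.0, size=30)
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a - b, alternative="two-sided", method="approx",
                           correction=False)
        # scipy standardizes the opposite tail; magnitudes must agree exactly
        assert abs(res.z_value) == pytest.approx(abs(float(ref.zstatistic)), abs=1e-9)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)


def _chain_adjacency(n):
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


def _brute_force_cluster_p(diffs, adjacency, cluster_alpha=0.05):
    """Independent oracle: full sign-flip enumeration with naive clustering."""
    n_part, n_sens = diffs.shape
    z_crit = sps.norm.ppf(1 - cluster_alpha / 2)

    def z_of(d):
        absd = np.abs(d)
        out = np.empty(n_sens)
        for s in range(n_sens):
            r = sps.rankdata(absd[:, s])
            t = float(np.sum(np.sign(d[:, s]) * r))
            out[s] = t / np.sqrt(np.sum(r**2))
        return out

    def clusters_of(z):
        found = []
        for sign in (1, -1):
            mask = sign * z > z_crit
            seen = set()
            for start in np.flatnonzero(mask):
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    i = stack.pop()
                    if i in comp:
                        continue
                    comp.add(i)
                    stack.extend(j for j in np.flatnonzero(adjacency[i])
                                 if mask[j] and j not in comp)
                seen |= comp
                found.append((frozenset(comp), float(z[list(comp)].sum())))
        return found

    observed = clusters_of(z_of(diffs))
    null = []
    for signs in itertools.product((1.0, -1.0), repeat=n_part):
        cl = clusters_of(z_of(np.array(signs)[:, None] * diffs))
        null.append(max((abs(m) for _, m in cl), default=0.0))
    null = np.array(null)
    return {sens: float(np.mean(null >= abs(m) - 1e-12)) for sens, m in observed}


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 8))
        adj = _chain_adjacency(8)
        res = cluster_permutation_test(a, a.copy(), adj, n_perm=200, seed=1)
        assert res.clusters == []
        assert np.allclose(res.z_values, 0.0)

    @pytest.mark.filterwarnings("ignore:n_perm")
    def test_matches_full_enumeration_oracle(self):
        # 6 participants, 6 sensors in a chain, effect on sensors 1-3
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.0, 1.0, size=(6, 6))
        diffs[:, 1:4] += 1.6
        adj = _chain_adjacency(6)
        res = cluster_permutation_test(diffs, np.zeros_like(diffs), adj,
                                       n_perm=64, seed=0)
        assert res.enumerated
        oracle = _brute_force_cluster_p(diffs, adj)
        assert len(res.clusters) == len(oracle)
        for c in res.clusters:
            assert oracle[frozenset(c.sensors)] == pytest.approx(c.p_value)

    def test_effect_cluster_confined_to_true_region(self, small_layout):
        # strong simulated effect on posterior sensors only
        rng = np.random.default_rng(9)
        n_pos = small_layout.n_positions
        post = set(small_layout.posterior_positions())
        a = rng.normal(0.1, 0.02, size=(10, n_pos))
        b = rng.normal(0.1, 0.02, size=(10, n_pos))
        cols = sorted(post)
        a[:, cols] += 0.4
        res = cluster_permutation_test(a, b, small_layout.adjacency,
                                       n_perm=500, seed=2)
        assert res.significant
        neighbours = {j for i in post
                      for j in np.flatnonzero(small_layout.adjacency[i])}
        for c in res.significant:
            assert set(c.sensors) <= post | neighbours
            assert c.mass > 0

    @pytest.mark.filterwarnings("ignore:n_perm")
    def test_participant_order_exchangeability_under_enumeration(self):
        rng = np.random.default_rng(3)
        a = rng.random((5, 6)) + np.array([0, 0.3, 0.3, 0, 0, 0])
        b = rng.random((5, 6))
        adj = _chain_adjacency(6)
        r1 = cluster_permutation_test(a, b, adj, n_perm=32, seed=0)
        perm = rng.permutation(5)
        r2 = cluster_permutation_test(a[perm], b[perm], adj, n_perm=32, seed=0)
        assert r1.enumerated and r2.enumerated
        p1 = {frozenset(c.sensors): c.p_value for c in r1.clusters}
        p2 = {frozenset(c.sensors): c.p_value for c in r2.clusters}
        assert p1 == p2

    def test_input_validation(self):
        adj = _chain_adjacency(4)
        with pytest.raises(ValueError, match="participants"):
            cluster_permutation_test(np.ones((1, 4)), np.ones((1, 4)), adj)
        with pytest.raises(ValueError, match="adjacency"):
            cluster_permutation_test(np.ones((3, 5)), np.zeros((3, 5)), adj)
        with pytest.warns(UserWarning, match="n_perm"):
            cluster_permutation_test(np.random.default_rng(0).random((3, 4)),
                                     np.random.default_rng(1).random((3, 4)),
                                     adj, n_perm=50)


def _synthetic_coeffs(rng, n_trials, n_sens=4, n_bins=3, signal=0.0):
    """White complex-Gaussian trial coefficients; optional phase-locked tag."""
    coeffs = (rng.standard_normal((n_trials, n_sens + 1, n_bins))
              + 1j * rng.standard_normal((n_trials, n_sens + 1, n_bins)))
    if signal:
        coeffs[:, :n_sens, 1] += signal          # common phase-locked component
        coeffs[:, n_sens, 1] += signal
    return TrialCoefficients(
        coeffs=coeffs, freqs_hz=np.array([59.0, 60.0, 61.0]),
        channel_ids=[f"s{i}" for i in range(n_sens)] + ["diode"],
        photodiode_channel_id="diode", window_s=(0.0, 1.0))


class TestParticipantPermutation:
    def test_noiseless_tag_against_noise_baseline_hits_resolution_floor(
            self, lownoise_epochs):
        base = trial_coefficients(lownoise_epochs, BASELINE_WINDOW_S)
        stim = trial_coefficients(lownoise_epochs, STIM_WINDOW_S)
        sensors = lownoise_epochs.channel_ids[:4]
        res = participant_permutation_test(base, stim, sensors, 60.0,
                                           n_perm=200, seed=0)
        assert res.significant
        assert res.p_value == pytest.approx(1 / 201)
        assert res.observed == pytest.approx(1.0, abs=1e-3)
        assert res.baseline_observed < 0.5

    def test_null_rejection_rate_near_nominal(self):
        # two independent noise draws in both roles: ~5 % rejections
        rng = np.random.default_rng(2024)
        n_reps, hits = 250, 0
        for _ in range(n_reps):
            base = _synthetic_coeffs(rng, 12)
            stim = _synthetic_coeffs(rng, 12)
            res = participant_permutation_test(
                base, stim, ["s0", "s1", "s2", "s3"], 60.0, n_perm=99, seed=rng)
            hits += res.significant
        rate = hits / n_reps
        # 3 sigma band around 0.05 for 250 Bernoulli trials
        assert 0.009 <= rate <= 0.091

    def test_null_p_values_super_uniform(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(150):
            base = _synthetic_coeffs(rng, 10)
            stim = _synthetic_coeffs(rng, 10)
            ps.append(participant_permutation_test(
                base, stim, ["s0", "s1"], 60.0, n_perm=79, seed=rng).p_value)
        ps = np.array(ps)
        grid = np.linspace(0.05, 0.95, 10)
        ecdf = np.array([(ps <= g).mean() for g in grid])
        assert np.all(ecdf <= grid + 0.12)          # MC tolerance

    def test_same_seed_identical_p(self):
        rng_data = np.random.default_rng(5)
        base = _synthetic_coeffs(rng_data, 10)
        stim = _synthetic_coeffs(rng_data, 10, signal=3.0)
        r1 = participant_permutation_test(base, stim, ["s0", "s1"], 60.0,
                                          n_perm=100, seed=11)
        r2 = participant_permutation_test(base, stim, ["s0", "s1"], 60.0,
                                          n_perm=100, seed=11)
        assert r1 == r2

    def test_rejection_probability_monotone_in_gain(self):
        # 3-point gain grid; power must not decrease with effect size
        rng = np.random.default_rng(31)
        rates = []
        for gain in (0.0, 1.0, 3.0):
            hits = 0
            for _ in range(100):
                base = _synthetic_coeffs(rng, 10)
                stim = _synthetic_coeffs(rng, 10, signal=gain)
                hits += participant_permutation_test(
                    base, stim, ["s0", "s1", "s2", "s3"], 60.0,
                    n_perm=60, seed=rng).significant
            rates.append(hits / 100)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.5

    def test_validation(self):
        rng = np.random.default_rng(0)
        base = _synthetic_coeffs(rng, 10)
        stim = _synthetic_coeffs(rng, 10)
        with pytest.raises(ValueError, match="empty"):
            participant_permutation_test(base, stim, [], 60.0)
        with pytest.raises(ValueError, match="2 trials"):
            participant_permutation_test(base.select_trials(np.arange(1)),
                                         stim, ["s0"], 60.0)


class TestSummaries:
    @pytest.mark.parametrize("left, right, expected",
                             [(0.3, 0.3, 0.0), (0.4, 0.2, 1 / 3), (0.5, 0.0, 1.0)])
    def test_lateralization_values(self, left, right, expected):
        assert lateralization_index(left, right).li == pytest.approx(expected)

    @settings(max_examples=40, deadline=None)
    @given(l=st.floats(0.001, 1.0), r=st.floats(0.001, 1.0))
    def test_lateralization_antisymmetry_and_bounds(self, l, r):
        fwd = lateralization_index(l, r).li
        rev = lateralization_index(r, l).li
        assert fwd == pytest.approx(-rev)
        assert -1.0 <= fwd <= 1.0
        assert np.sign(fwd) == np.sign(l - r)

    def test_lateralization_undefined_for_double_zero(self):
        with pytest.raises(DegenerateTestError):
            lateralization_index(0.0, 0.0)

    def test_slope_exact_line_and_constant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, se = fit_condition_slope(x, 2 * x + 1)
        assert slope == pytest.approx(2.0) and se == pytest.approx(0.0)
        slope, se = fit_condition_slope(x, np.full(4, 3.3))
        assert slope == pytest.approx(0.0)
        with pytest.raises(ValueError, match="constant"):
            fit_condition_slope(np.ones(4), 2 * x)

    def test_proportion_significant(self):
        assert proportion_significant([True] * 11) == 100.0
        assert proportion_significant([False] * 5) == 0.0
        assert proportion_significant([True] * 4 + [False] * 7) == pytest.approx(
            36.36, abs=0.01)
        with pytest.raises(ValueError):
            proportion_significant([])
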