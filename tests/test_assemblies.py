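"""Assembly detection, activation algebra, reactivation analytics."""

import numpy as np
import pandas as pd
import pytest

from condpipe import assemblies as A
from condpipe.synthetic import AssemblyDef, generate_session
from conftest import small_spec


@pytest.fixture(scope="module")
def coupled_session():
    """CA1 session with one ripple-coupled (CS--biased) and one uncoupled
    (CS+-biased) assembly, plus detected model and activation trace."""
    spec = small_spec(seed=13, n_units_ca1=24, n_units_pfc=4,
                      n_trials_csplus=15, n_trials_csminus=15,
                      iti_range_s=(10.0, 14.0), ripple_rate_hz=0.2,
                      assembly_defs=[
                          AssemblyDef("ca1", tuple(range(6)),
                                      ripple_coupling_p=0.5, bias_cs="minus"),
                          AssemblyDef("ca1", tuple(range(6, 12)),
                                      ripple_coupling_p=0.0, bias_cs="plus"),
                          AssemblyDef("ca1", tuple(range(12, 18)),
                                      ripple_coupling_p=0.0)])
    bundle, truth = generate_session(spec)
    model = A.detect_assemblies(bundle, "ca1", seed=0)
    trace = A.assembly_activation(model, bundle.spikes["ca1"], 0.0,
                                  bundle.duration_s)
    return spec, bundle, truth, model, trace


class TestMPBound:
    def test_closed_form(self):
        assert A.mp_bound(100, 10000) == pytest.approx(1.21)

    def test_degenerate_sizes_raise(self):
        with pytest.raises(ValueError):
            A.mp_bound(100, 100)
        with pytest.raises(ValueError):
            A.mp_bound(100, 50)

    def test_gaussian_null_rarely_exceeds_bound(self):
        """z-scored i.i.d. Gaussian matrices almost never produce an
        eigenvalue above the analytic edge (20 units x 5000 bins)."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((5000, 20))
            Z = (Z - Z.mean(0)) / Z.std(0)
            ev = np.linalg.eigvalsh((Z.T @ Z) / 5000)
            hits += np.any(ev > A.mp_bound(20, 5000))
        assert hits <= round(0.15 * n_seeds)


class TestDetection:
    def test_planted_assemblies_counted_and_matched(self, post_session):
        """Three planted CA1 assemblies: exact count and matched-pattern
        cosine similarity > 0.9 each."""
        _, bundle, truth = post_session
        model = A.detect_assemblies(bundle, "ca1", seed=0)
        tw = np.array([a["weights"] for a in truth.assembly_membership
                       if a["area"] == "ca1"])
        assert model.n_assemblies == len(tw) == 3
        pairs = A.match_patterns(model.patterns, tw)
        assert len(pairs) == 3
        assert all(s > 0.9 for _, _, s in pairs)

    def test_patterns_unit_norm_and_sign_aligned(self, post_session):
        _, bundle, _ = post_session
        model = A.detect_assemblies(bundle, "pfc", seed=0)
        for p in model.patterns:
            assert np.linalg.norm(p) == pytest.approx(1.0)
            assert p[np.argmax(np.abs(p))] > 0

    def test_detection_is_seed_stable(self, post_session):
        _, bundle, _ = post_session
        m1 = A.detect_assemblies(bundle, "ca1", seed=4)
        m2 = A.detect_assemblies(bundle, "ca1", seed=4)
        assert np.array_equal(m1.patterns, m2.patterns)

    def test_assembly_free_population_yields_empty_model(self, null_session):
        _, bundle, _ = null_session
        model = A.detect_assemblies(bundle, "ca1", seed=0)
        assert model.n_assemblies == 0
        assert model.patterns.shape == (0, 30)

    def test_duplicated_unit_drives_eigenvalue_above_bound(self):
        """A unit cloned into the population creates a correlated pair and
        one above-bound eigenvalue."""
        spec = small_spec(seed=17, n_units_ca1=10, n_units_pfc=2)
        bundle, _ = generate_session(spec)
        bundle.spikes["ca1"].append(bundle.spikes["ca1"][0].copy())
        model = A.detect_assemblies(bundle, "ca1", seed=0)
        assert model.n_assemblies >= 1
        top = model.patterns[0]
        heavy = np.argsort(np.abs(top))[-2:]
        assert set(heavy) == {0, 10}


class TestActivationAlgebra:
    def test_single_unit_activity_is_zero(self):
        w = np.full(10, 1 / np.sqrt(10))
        z = np.zeros(10)
        z[3] = 5.0
        assert A.activation_strength(z, w) == 0.0

    def test_two_member_hand_value(self):
        # weights 0.7/0.7, z-values 2/2 -> 2 * 0.7*0.7*2*2 = 3.92
        w = np.array([0.7, 0.7, 0.0])
        z = np.array([2.0, 2.0, 0.0])
        assert A.activation_strength(z, w) == pytest.approx(3.92, abs=1e-12)

    def test_matches_explicit_projector(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=8)
        w /= np.linalg.norm(w)
        z = rng.normal(size=8)
        P = np.outer(w, w)
        np.fill_diagonal(P, 0.0)
        assert A.activation_strength(z, w) == pytest.approx(z @ P @ z)


class TestActivationTrace:
    def test_peaks_align_with_planted_events(self, coupled_session):
        """Strong activation peaks land within one bin (20 ms) of planted
        synchronous events."""
        spec, bundle, truth, model, trace = coupled_session
        tw = np.array([a["weights"] for a in truth.assembly_membership])
        pairs = A.match_patterns(model.patterns, tw)
        det = {t: d for d, t, _ in pairs}
        for truth_idx, asm in enumerate(truth.assembly_membership):
            act = trace.activation[det[truth_idx]]
            thr = np.percentile(act, 99.9)
            peak_times = trace.times[act > thr]
            events = asm["event_times"] + 0.01    # events span [t, t+20 ms)
            lags = [np.min(np.abs(events - t)) for t in peak_times]
            assert np.median(lags) < 0.02

    def test_unit_mismatch_raises(self, coupled_session):
        *_, model, _ = coupled_session
        with pytest.raises(ValueError, match="mismatch"):
            A.assembly_activation(model, [np.array([1.0])] * 3, 0.0, 10.0)


class TestSWRReactivation:
    def test_coupled_exceeds_uncoupled(self, coupled_session):
        spec, bundle, truth, model, trace = coupled_session
        tw = np.array([a["weights"] for a in truth.assembly_membership])
        det = {t: d for d, t, _ in A.match_patterns(model.patterns, tw)}
        summ = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                            bundle.trials)
        assert summ.mean_reactivation[det[0]] > 1.0       # coupled
        assert abs(summ.mean_reactivation[det[1]]) < 0.5  # uncoupled

    def test_shuffled_ripple_times_abolish_reactivation(self, coupled_session):
        spec, bundle, truth, model, trace = coupled_session
        rng = np.random.default_rng(2)
        iti = A._iti_mask(trace.times, bundle.trials)
        fake = np.sort(rng.choice(trace.times[iti],
                                  size=len(truth.ripple_times_s),
                                  replace=False))
        summ = A.swr_triggered_reactivation(trace, fake, bundle.trials)
        assert np.all(np.abs(summ.mean_reactivation) < 0.5)

    def test_baseline_excludes_ripple_centers(self, coupled_session):
        """Injecting a huge activation only inside the ripple windows does
        not change the z baseline."""
        spec, bundle, truth, model, trace = coupled_session
        import copy
        boosted = copy.deepcopy(trace)
        for t in truth.ripple_times_s:
            idx = np.abs(boosted.times - t) <= 0.025
            boosted.activation[:, idx] += 1e4
        s0 = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                          bundle.trials)
        s1 = A.swr_triggered_reactivation(boosted, truth.ripple_times_s,
                                          bundle.trials)
        # baseline (mu, sd) unchanged => the boost propagates linearly into
        # the center-window z values
        assert np.all(s1.mean_reactivation > s0.mean_reactivation + 100)

    def test_no_ripples_empty_summary(self, coupled_session):
        *_, trace = coupled_session
        bundle = coupled_session[1]
        summ = A.swr_triggered_reactivation(trace, np.empty(0), bundle.trials)
        assert summ.per_ripple.shape[1] == 0


class TestStimulusAlignedActivation:
    def test_biased_assembly_discriminates_cs(self, coupled_session):
        spec, bundle, truth, model, trace = coupled_session
        tw = np.array([a["weights"] for a in truth.assembly_membership])
        det = {t: d for d, t, _ in A.match_patterns(model.patterns, tw)}
        sta = A.stimulus_triggered_activation(trace, bundle.trials)
        # assembly 1 is CS+-biased: stimulus+trace activity higher on CS+
        k = det[1]
        plus = sta["period_means"]["plus"]
        minus = sta["period_means"]["minus"]
        assert plus["stim"][k] + plus["trace"][k] \
            > minus["stim"][k] + minus["trace"][k]

    def test_baseline_period_mean_is_zero(self, coupled_session):
        _, bundle, _, _, trace = coupled_session
        sta = A.stimulus_triggered_activation(trace, bundle.trials)
        both = np.r_[sta["period_means"]["plus"]["baseline"],
                     sta["period_means"]["minus"]["baseline"]]
        assert np.all(np.abs(both) < 0.2)


class TestModulationScores:
    def make_trace(self, plus_level, minus_level, trials):
        times = np.arange(0.0, trials["onset_s"].max() + 5.0, 0.01)
        act = np.zeros((1, len(times)))
        for _, tr in trials.iterrows():
            m = (times >= tr.onset_s) & (times < tr.onset_s + 3.0)
            act[0, m] = plus_level if tr.cs_type == "plus" else minus_level
        return A.ActivationTrace(times, act, 0.02, 0.01)

    def trials_frame(self):
        return pd.DataFrame({"onset_s": [10.0, 20.0, 30.0, 40.0],
                             "cs_type": ["plus", "minus", "plus", "minus"],
                             "reward_time_s": [13.0, np.nan, 33.0, np.nan]})

    def test_score_arithmetic(self):
        trials = self.trials_frame()
        trace = self.make_trace(2.0, 0.5, trials)
        scores = A.modulation_scores(trace, trials)
        assert scores["trial_type"][0] == pytest.approx(1.5, abs=0.01)

    def test_selection_returns_one_per_category(self):
        sel = A.select_extreme_assemblies(np.array([-2.0, 0.1, 3.0, -0.5]))
        assert sel["cs_plus_suppressed"] == 0
        assert sel["cs_minus_suppressed"] == 2
        assert sel["nonmodulated"] == 1
        assert not sel["flagged"]
        assert A.select_extreme_assemblies(np.array([1.0, 2.0]))["flagged"]

    def test_correlation_direction_with_planted_coupling(self, coupled_session):
        """Ripple coupling planted on the CS+-suppressed assembly gives a
        negative score-vs-reactivation correlation."""
        spec, bundle, truth, model, trace = coupled_session
        summ = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                            bundle.trials)
        scores = A.modulation_scores(trace, bundle.trials)
        res = A.reactivation_vs_modulation(summ.mean_reactivation,
                                           scores["trial_type"])
        assert res["r"] < 0

    def test_too_few_assemblies_raise(self):
        with pytest.raises(ValueError):
            A.reactivation_vs_modulation([1.0, 2.0], [0.5, 0.1])


class TestBlockDynamics:
    def test_blocks_partition_trials_evenly(self, coupled_session):
        _, bundle, truth, _, trace = coupled_session
        summ = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                            bundle.trials)
        bd = A.block_dynamics(summ, bundle.trials, bundle.duration_s)
        assert summ.per_ripple.shape[0] == bd["per_block"].shape[0]
        assert bd["per_block"].shape[1] == 10
        sizes = [len(s) for s in np.array_split(np.arange(len(bundle.trials)), 10)]
        assert max(sizes) - min(sizes) <= 1

    def test_ramped_coupling_increases_over_blocks(self):
        """Linearly increasing ripple coupling raises late-block
        reactivation above early blocks."""
        spec = small_spec(seed=19, n_units_ca1=24, n_units_pfc=4,
                          n_trials_csplus=20, n_trials_csminus=20,
                          iti_range_s=(10.0, 14.0), ripple_rate_hz=0.25,
                          assembly_defs=[
                              AssemblyDef("ca1", tuple(range(6)),
                                          ripple_coupling_p=0.4,
                                          coupling_ramp=True)])
        bundle, truth = generate_session(spec)
        model = A.detect_assemblies(bundle, "ca1", seed=0)
        trace = A.assembly_activation(model, bundle.spikes["ca1"], 0.0,
                                      bundle.duration_s)
        summ = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                            bundle.trials)
        bd = A.block_dynamics(summ, bundle.trials, bundle.duration_s)
        plus = bd["tests"]["reactivation+"]
        assert np.nanmean(plus["last3"]) > np.nanmean(plus["first3"])

    def test_too_few_trials_raise(self, coupled_session):
        _, bundle, truth, _, trace = coupled_session
        summ = A.swr_triggered_reactivation(trace, truth.ripple_times_s,
                                            bundle.trials)
        with pytest.raises(ValueError):
            A.block_dynamics(summ, bundle.trials.head(5), bundle.duration_s)


class TestSignificantFraction:
    def test_normal_tail_value(self):
        rng = np.random.default_rng(0)
        frac, flagged = A.significant_reactivation_fraction(
            rng.standard_normal(200_000))
        assert not flagged
        assert frac == pytest.approx(0.0228, abs=0.003)

    def test_constant_values_mad_zero_path(self):
        frac, flagged = A.significant_reactivation_fraction(np.ones(50))
        assert flagged and frac == 0.0

    def test_heavy_right_tail(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(10_000)
        v[:1000] = 10.0
        frac, _ = A.significant_reactivation_fraction(v)
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_too_few_ripples_raise(self):
        with pytest.raises(ValueError):
            A.significant_reactivation_fraction(np.arange(5))


class TestQuadrants:
    def test_independent_reactivations_near_25_25(self):
        rng = np.random.default_rng(2)
        ca1 = rng.standard_normal((3, 400))
        pfc = rng.standard_normal((2, 400))
        q = A.quadrant_coactivation(ca1, pfc)
        assert q["q1_mean_pct"] == pytest.approx(25.0, abs=5.0)
        assert q["q2_mean_pct"] == pytest.approx(25.0, abs=5.0)

    def test_comonotone_pair_is_50_0(self):
        x = np.arange(100, dtype=float)
        q = A.quadrant_coactivation(x[None, :], x[None, :])
        assert q["q1_mean_pct"] == 50.0
        assert q["q2_mean_pct"] == 0.0

    def test_anticorrelated_pair_has_empty_q1(self):
        x = np.arange(100, dtype=float)
        q = A.quadrant_coactivation(x[None, :], -x[None, :])
        assert q["q1_mean_pct"] == 0.0
        assert q["q2_mean_pct"] == 50.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="share"):
            A.quadrant_coactivation(np.zeros((1, 20)), np.zeros((1, 30)))
        with pytest.raises(ValueError, match="10"):
            A.quadrant_coactivation(np.zeros((1, 5)), np.zeros((1, 5)))
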