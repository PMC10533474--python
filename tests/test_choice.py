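import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo import behavior, choice, synth
from gonogo.choice import (
    ChoiceResult,
    SessionIneligibleError,
    WINDOW_EARLY,
    WINDOW_FULL,
)
from gonogo.synth import SimConfig

from conftest import make_session


def roc_brute_force(fa, cr):
    """All-pairs oracle: mean of 1(fa > cr) + 0.5 * 1(fa == cr)."""
    total = 0.0
    for x in fa:
        for y in cr:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(fa) * len(cr))


class TestRocArea:
    @pytest.mark.parametrize(
        "fa, cr, expected",
        [
            ([3.0, 3.0], [3.0, 3.0], 0.5),  # all ties
            ([2, 3], [0, 1], 1.0),  # complete separation
            ([1, 2], [1, 3], 0.375),  # (0.5 + 0 + 1 + 0) / 4
        ],
    )
    def test_known_values(self, fa, cr, expected):
        assert choice.roc_area(fa, cr) == expected

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            choice.roc_area([], [1.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        fa=st.lists(st.integers(0, 6), min_size=1, max_size=15),
        cr=st.lists(st.integers(0, 6), min_size=1, max_size=15),
    )
    def test_rank_identity_equals_brute_force_exactly(self, fa, cr):
        """Mann-Whitney rank formula == all-pairs count, heavy ties."""
        assert choice.roc_area(fa, cr) == roc_brute_force(fa, cr)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        fa = rng.integers(0, 10, size=12).astype(float)
        cr = rng.integers(0, 10, size=9).astype(float)
        base = choice.roc_area(fa, cr)
        for f in (np.exp, np.sqrt, lambda v: 3 * v + 7):
            assert choice.roc_area(f(fa), f(cr)) == pytest.approx(base)


class TestChoicePreference:
    def test_range_endpoints(self):
        assert choice.choice_preference([5, 6], [1, 2]) == 1.0
        assert choice.choice_preference([1, 2], [5, 6]) == -1.0

    def test_derived_example(self):
        assert choice.choice_preference([1, 2], [1, 3]) == pytest.approx(-0.25)

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 8), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    def test_antisymmetry_exact(self, a, b):
        assert choice.choice_preference(a, b) == -choice.choice_preference(b, a)


class TestEligibility:
    def test_waiting_lick_trials_excluded(self):
        s = make_session(
            [
                ("NOGO", "OFF", [0.2, 0.6]),  # FA with waiting lick: excluded
                ("NOGO", "OFF", [0.6]),  # FA, eligible
                ("NOGO", "OFF", []),  # CR, eligible
                ("NOGO", "OFF", [0.1]),  # CR with waiting lick: excluded
                ("GO", "OFF", [0.8]),
            ]
        )
        fa_idx, cr_idx = choice.eligible_nogo_trials(s)
        assert list(fa_idx) == [1] and list(cr_idx) == [2]

    def test_nine_eligible_fa_trials_excluded(self):
        specs = [("NOGO", "OFF", [0.6])] * 9 + [("NOGO", "OFF", [])] * 20
        s = make_session(specs)
        with pytest.raises(SessionIneligibleError) as exc_info:
            choice.unit_choice_result(np.zeros(s.n_trials), s)
        assert exc_info.value.eligibility.n_eligible_fa == 9

    def test_no_wait_lick_simulation_all_eligible(self):
        cfg = SimConfig(n_trials=80, seed=2, p_wait_lick=0.0)
        s = synth.generate_session(cfg)
        behavior.classify_outcomes(s)
        fa_idx, cr_idx = choice.eligible_nogo_trials(s)
        n_nogo = sum(t.stimulus.value == "NOGO" for t in s.trials)
        assert fa_idx.size + cr_idx.size == n_nogo


class TestUnitChoiceResult:
    def test_positive_gain_yields_positive_preference(self):
        cfg = SimConfig(n_trials=300, seed=3, choice_gain=2.0, p_wait_lick=0.0)
        s = synth.generate_session(cfg)
        behavior.classify_outcomes(s)
        unit = synth.generate_spikes(s, cfg)
        res = choice.unit_choice_result(
            choice.spike_window_values(unit, s), s)
        assert res.choice_pref > 0.2
        assert res.choice_pref == pytest.approx(2 * (res.roc_area - 0.5))

    def test_early_window_uses_first_300ms(self, nogo_session):
        s = nogo_session
        # spikes only at 0.4 s: counted by the full window, not the early one
        unit_times = [t.onset + 0.4 for t in s.trials]
        from gonogo.core import SpikeUnit

        unit = SpikeUnit("u", np.sort(unit_times))
        full = choice.spike_window_values(unit, s, WINDOW_FULL)
        early = choice.spike_window_values(unit, s, WINDOW_EARLY)
        assert full.sum() == s.n_trials and early.sum() == 0


class TestBinnedCorrelation:
    def test_exactly_linear_bin_means_give_r_one(self):
        results = [
            (ChoiceResult(0.5, pref, 12, 12), cr)
            for pref, cr in [(0.1, 0.25), (0.2, 0.35), (0.3, 0.45), (0.4, 0.55)]
        ]
        corr = choice.binned_correlation(results)
        assert corr.r == pytest.approx(1.0)

    def test_worked_bin_membership(self):
        """CR rates of 41% and 46% share the (40%, 50%] bin."""
        results = [
            (ChoiceResult(0.5, 0.1, 12, 12), 0.41),
            (ChoiceResult(0.5, 0.3, 12, 12), 0.46),
            (ChoiceResult(0.5, 0.0, 12, 12), 0.25),
            (ChoiceResult(0.5, 0.5, 12, 12), 0.65),
        ]
        corr = choice.binned_correlation(results)
        assert corr.bin_centers.tolist() == [25.0, 45.0, 65.0]
        assert corr.bin_means[1] == pytest.approx(0.2)
        assert corr.bin_ns.tolist() == [1, 2, 1]

    def test_right_edge_belongs_to_bin(self):
        results = [
            (ChoiceResult(0.5, 0.1, 12, 12), 0.50),  # exactly 50% -> (40, 50]
            (ChoiceResult(0.5, 0.2, 12, 12), 0.25),
            (ChoiceResult(0.5, 0.3, 12, 12), 0.65),
        ]
        corr = choice.binned_correlation(results)
        assert 45.0 in corr.bin_centers

    def test_fewer_than_three_bins_errors(self):
        res = ChoiceResult(0.5, 0.1, 12, 12)
        with pytest.raises(ValueError):
            choice.binned_correlation([(res, 0.25), (res, 0.35)])


class TestDeltaChoicePreference:
    def test_identical_gives_zero_and_sign_flip(self):
        off = ChoiceResult(0.6, 0.2, 15, 15)
        on = ChoiceResult(0.6, 0.2, 14, 16)
        assert choice.delta_choice_preference(off, on) == 0.0
        on2 = ChoiceResult(0.4, -0.2, 14, 16)
        assert choice.delta_choice_preference(off, on2) == -(
            choice.delta_choice_preference(on2, off)
        )

    def test_window_mismatch_errors(self):
        off = ChoiceResult(0.6, 0.2, 15, 15, WINDOW_FULL)
        on = ChoiceResult(0.6, 0.2, 15, 15, WINDOW_EARLY)
        with pytest.raises(ValueError):
            choice.delta_choice_preference(off, on)

    def test_laser_removing_choice_gain_yields_negative_delta(self):
        """If the laser abolishes the choice signal, the ON-OFF
        preference difference is negative on average."""
        deltas = []
        for seed in range(8):
            cfg_off = SimConfig(n_trials=300, seed=seed, choice_gain=2.0,
                                p_wait_lick=0.0)
            cfg_on = SimConfig(n_trials=300, seed=seed, choice_gain=1.0,
                               p_wait_lick=0.0)
            s = synth.generate_session(cfg_off)
            behavior.classify_outcomes(s)
            u_off = synth.generate_spikes(s, cfg_off)
            u_on = synth.generate_spikes(s, cfg_on)
            r_off = choice.unit_choice_result(
                choice.spike_window_values(u_off, s), s)
            r_on = choice.unit_choice_result(
                choice.spike_window_values(u_on, s), s)
            deltas.append(choice.delta_choice_preference(r_off, r_on))
        assert np.mean(deltas) < -0.1
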