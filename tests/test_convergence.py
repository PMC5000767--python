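import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confconv import (
    ConvergenceRule,
    ConvergenceTrace,
    ThermalContext,
    combined_converged_after,
    converged_after,
    ensemble_from_barriers,
    evaluated_trace,
    ordering_sensitivity,
    running_statistic,
)

from conftest import direct_boltzmann


def trace_from_changes(changes, first_n=1):
    """Build a minimal trace with prescribed step changes (values unused)."""
    points = tuple((first_n + i, 0.0) for i in range(len(changes) + 1))
    chg = tuple((first_n + 1 + i, c) for i, c in enumerate(changes))
    return ConvergenceTrace("boltzmann_average", points, chg)


class TestRunningStatistic:
    def test_constant_barriers_give_flat_trace(self):
        ens = ensemble_from_barriers([8.0] * 10)
        tr = running_statistic(ens, "boltzmann_average")
        assert [v for _, v in tr.points] == pytest.approx([8.0] * 10)
        assert all(c == 0.0 for _, c in tr.changes)

    def test_prefix_values_match_statistic_oracle(self):
        barriers = [10.0, 20.0, 15.0]
        tr = running_statistic(ensemble_from_barriers(barriers), "boltzmann_average")
        assert tr.points[0] == (1, pytest.approx(10.0))
        assert tr.points[1][1] == pytest.approx(direct_boltzmann([10.0, 20.0]))
        assert tr.points[2][1] == pytest.approx(direct_boltzmann(barriers))

    def test_changes_are_percent_of_previous_value(self):
        tr = running_statistic(ensemble_from_barriers([10.0, 20.0]), "boltzmann_average")
        (n, change), = tr.changes
        v1, v2 = tr.points[0][1], tr.points[1][1]
        assert n == 2
        assert change == pytest.approx(abs(v2 - v1) / v1 * 100)

    def test_absolute_metric(self):
        rule = ConvergenceRule(change_metric="absolute")
        tr = running_statistic(
            ensemble_from_barriers([10.0, 20.0]), "boltzmann_average", rule=rule
        )
        v1, v2 = (v for _, v in tr.points)
        assert tr.changes[0][1] == pytest.approx(abs(v2 - v1))

    def test_de_trace_starts_at_two(self):
        tr = running_statistic(ensemble_from_barriers([10.0, 12.0, 14.0]),
                               "disproportionate_effect")
        assert tr.points[0][0] == 2
        assert len(tr.changes) == len(tr.points) - 1

    def test_reversal_changes_trace_but_not_final_point(self):
        barriers = [10.0, 20.0, 15.0, 12.0]
        fwd = running_statistic(ensemble_from_barriers(barriers), "boltzmann_average")
        rev = running_statistic(ensemble_from_barriers(barriers[::-1]), "boltzmann_average")
        assert fwd.points[-1][1] == pytest.approx(rev.points[-1][1], rel=1e-12)
        assert fwd.points[0][1] != rev.points[0][1]

    def test_too_few_records_for_de(self):
        with pytest.raises(ValueError, match="at least 2"):
            running_statistic(ensemble_from_barriers([10.0]), "disproportionate_effect")


class TestConvergedAfter:
    def test_constant_trace_converges_when_window_completes(self):
        tr = trace_from_changes([0.0] * 6)
        # window of 5 zero-changes completes at the 6th conformation
        assert converged_after(tr, ConvergenceRule()) == 6
        assert converged_after(tr, ConvergenceRule(count_from="window_start")) == 1

    def test_never_quiet_trace_returns_none(self):
        tr = trace_from_changes([7.0] * 12)
        assert converged_after(tr, ConvergenceRule()) is None

    def test_window_must_fit_entirely_inside_trace(self):
        # 6 points, changes 10,1,1,1,1: the only quiet run is 4 long
        tr = trace_from_changes([10.0, 1.0, 1.0, 1.0, 1.0])
        assert converged_after(tr, ConvergenceRule()) is None
        assert converged_after(tr, ConvergenceRule(count_from="window_start")) is None

    def test_first_quiet_window_wins(self):
        tr = trace_from_changes([9.0, 1.0, 1.0, 1.0, 1.0, 1.0, 9.0, 1.0])
        # quiet window is changes at n=3..7, confirming point n=2
        assert converged_after(tr, ConvergenceRule()) == 7
        assert converged_after(tr, ConvergenceRule(count_from="window_start")) == 2

    def test_threshold_is_strict(self):
        tr = trace_from_changes([5.0] * 8)
        assert converged_after(tr, ConvergenceRule(threshold=5.0)) is None
        assert converged_after(tr, ConvergenceRule(threshold=5.01)) == 6

    @given(st.lists(st.floats(min_value=0, max_value=20, allow_nan=False),
                    min_size=5, max_size=40),
           st.floats(min_value=0.5, max_value=15),
           st.floats(min_value=0, max_value=10))
    @settings(deadline=None, max_examples=80)
    def test_monotone_in_threshold(self, changes, thr, bump):
        tr = trace_from_changes(changes)
        lo = converged_after(tr, ConvergenceRule(threshold=thr))
        hi = converged_after(tr, ConvergenceRule(threshold=thr + bump))
        inf = float("inf")
        assert (hi if hi is not None else inf) <= (lo if lo is not None else inf)

    @given(st.lists(st.floats(min_value=0, max_value=20, allow_nan=False),
                    min_size=5, max_size=40),
           st.integers(min_value=1, max_value=8))
    @settings(deadline=None, max_examples=80)
    def test_antitone_in_window(self, changes, w):
        tr = trace_from_changes(changes)
        short = converged_after(tr, ConvergenceRule(window=w))
        longer = converged_after(tr, ConvergenceRule(window=w + 1))
        inf = float("inf")
        assert (longer if longer is not None else inf) >= (
            short if short is not None else inf
        )


class TestCombined:
    def test_constant_ensemble_waits_for_de_window(self):
        ens = ensemble_from_barriers([9.0] * 12)
        # DE trace starts at n=2; its window of 5 changes completes at n=7
        assert combined_converged_after(ens) == 7
        rule = ConvergenceRule(count_from="window_start")
        assert combined_converged_after(ens, rule) == 2

    def test_combined_is_max_of_individual_counts(self, random_barriers):
        ens = ensemble_from_barriers(random_barriers(20, seed=11, low=14, high=22))
        rule = ConvergenceRule()
        counts = []
        for stat in ("boltzmann_average", "disproportionate_effect"):
            tr = evaluated_trace(ens, stat, rule)
            counts.append(tr.converged_after)
        combined = combined_converged_after(ens, rule)
        if None in counts:
            assert combined is None
        else:
            assert combined == max(counts)
            assert all(combined >= c for c in counts)

    def test_unsettled_de_propagates_none(self):
        # alternating near/far minima keep the DE trace jumping
        barriers = [10.0, 30.0, 9.0, 30.0, 8.0, 30.0, 7.0, 30.0, 6.0, 30.0]
        assert combined_converged_after(ensemble_from_barriers(barriers)) is None


class TestOrderingSensitivity:
    def test_constant_ensemble_is_order_insensitive(self):
        ens = ensemble_from_barriers([9.0] * 12)
        counts = ordering_sensitivity(ens, n_permutations=10, seed=5)
        assert set(counts) == {7}

    def test_same_seed_reproduces_distribution(self, random_barriers):
        ens = ensemble_from_barriers(random_barriers(15, seed=8, low=14, high=22))
        a = ordering_sensitivity(ens, n_permutations=20, seed=42)
        b = ordering_sensitivity(ens, n_permutations=20, seed=42)
        assert a == b

    def test_zero_permutations_rejected(self):
        ens = ensemble_from_barriers([9.0] * 5)
        with pytest.raises(ValueError, match="n_permutations"):
            ordering_sensitivity(ens, n_permutations=0, seed=1)
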