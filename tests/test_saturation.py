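import itertools
from collections import Counter

import numpy as np
import pytest

from polyamp.io import AbundanceProfile, Kingdom, LineageRecord
from polyamp.saturation import (
    AccumulationState,
    CountVector,
    SaturationParams,
    SaturationStatus,
    chao1,
    extrapolate,
    is_saturated,
    rarefaction_curve,
    rarefy,
    stop_recommendation,
    update_accumulation,
)


def mc_rarefy(cv: CountVector, m: int, reps: int, rng) -> tuple[float, float]:
    """Monte-Carlo subsampling oracle: mean and SE of distinct species."""
    pop = np.repeat(np.arange(cv.s_obs), cv.counts)
    keys = rng.random((reps, cv.n))
    picks = pop[np.argsort(keys, axis=1)[:, :m]]
    distinct = np.array([len(np.unique(row)) for row in picks])
    return float(distinct.mean()), float(distinct.std(ddof=1) / np.sqrt(reps))


def _profile(species_counts, kingdom=Kingdom.bacteria, sample_id="bc"):
    p = AbundanceProfile(sample_id, kingdom)
    for i, (name, n) in enumerate(species_counts.items()):
        tax_id = f"t{name}"
        p.counts[(tax_id, 6)] = n
        p.lineages[tax_id] = LineageRecord(
            tax_id, ("B", "P", "C", "O", "F", "G", name, ""), kingdom
        )
    return p


class TestRarefy:
    def test_one_read_yields_one_species(self):
        assert rarefy(CountVector.from_counts([5, 3, 2]), 1) == pytest.approx(1.0)

    def test_small_case_equals_exhaustive_enumeration(self):
        """counts [2,2], m=2: average distinct species over all C(4,2) pairs."""
        pop = [0, 0, 1, 1]
        subsets = list(itertools.combinations(range(4), 2))
        expected = np.mean([len({pop[i] for i in s}) for s in subsets])
        assert expected == pytest.approx(5 / 3)
        assert rarefy(CountVector.from_counts([2, 2]), 2) == pytest.approx(expected)

    def test_full_sample_returns_observed_richness(self):
        cv = CountVector.from_counts([7, 2, 1, 1])
        assert rarefy(cv, cv.n) == pytest.approx(cv.s_obs)

    def test_out_of_range_m_rejected(self):
        cv = CountVector.from_counts([2, 2])
        with pytest.raises(ValueError):
            rarefy(cv, 5)
        with pytest.raises(ValueError):
            rarefy(cv, 0)

    def test_matches_monte_carlo_oracle(self, rng):
        """Analytic rarefaction vs 10,000-rep subsampling on random vectors."""
        for _ in range(20):
            s = int(rng.integers(2, 15))
            counts = rng.integers(1, 30, size=s)
            cv = CountVector.from_counts(counts[: max(1, s)])
            if cv.n > 200:
                cv = CountVector.from_counts(np.minimum(counts, 200 // s) + 1)
            m = int(rng.integers(1, cv.n + 1))
            mc_mean, mc_se = mc_rarefy(cv, m, 10_000, rng)
            assert rarefy(cv, m) == pytest.approx(mc_mean, abs=max(3 * mc_se, 1e-6))

    def test_non_decreasing_and_concave(self, rng):
        for _ in range(5):
            counts = rng.integers(1, 20, size=int(rng.integers(2, 10)))
            cv = CountVector.from_counts(counts)
            values = [rarefy(cv, m) for m in range(1, cv.n + 1)]
            diffs = np.diff(values)
            assert (diffs >= -1e-9).all()
            assert (np.diff(diffs) <= 1e-9).all()


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 3, 3], 3.0),        # no singletons: estimate is S_obs
            ([1, 1, 2], 3.5),        # 3 + 2*1/(2*2)
            ([1], 1.0),
            ([1, 1, 1], 3 + 3 * 2 / 2),  # f1=3, f2=0 -> +3
        ],
    )
    def test_closed_form(self, counts, expected):
        assert chao1(CountVector.from_counts(counts)) == pytest.approx(expected)


class TestExtrapolate:
    def test_flat_when_no_singletons(self):
        cv = CountVector.from_counts([2, 3, 4])
        assert extrapolate(cv, 100) == pytest.approx(cv.s_obs)

    def test_limit_is_chao1(self):
        cv = CountVector.from_counts([1, 1, 2])
        assert extrapolate(cv, 10_000_000) == pytest.approx(chao1(cv), abs=1e-9)

    def test_closed_form_value(self):
        cv = CountVector.from_counts([1, 1, 2])  # n=4, S=3, f1=2, f0=0.5
        m = 8
        f0, f1, n = 0.5, 2, 4
        expected = 3 + f0 * (1 - (1 - f1 / (n * f0 + f1)) ** (m - n))
        assert extrapolate(cv, m) == pytest.approx(expected)

    def test_continuous_at_boundary(self):
        cv = CountVector.from_counts([1, 1, 2, 5])
        assert extrapolate(cv, cv.n + 1) >= cv.s_obs
        assert extrapolate(cv, cv.n + 1) - cv.s_obs < 1.0

    def test_bounded_by_chao1(self, rng):
        for _ in range(10):
            counts = rng.integers(1, 10, size=int(rng.integers(2, 12)))
            cv = CountVector.from_counts(counts)
            for m in (cv.n + 1, 2 * cv.n, 10 * cv.n):
                assert extrapolate(cv, m) <= chao1(cv) + 1e-9

    def test_curve_mixes_interpolation_and_extrapolation(self):
        cv = CountVector.from_counts([4, 3, 1])
        curve = rarefaction_curve(cv, [1, cv.n, 2 * cv.n])
        assert curve.extrapolated == (False, False, True)
        assert curve.expected_richness[0] == pytest.approx(1.0)
        assert curve.expected_richness[1] == pytest.approx(cv.s_obs)


class TestUpdateAccumulation:
    def test_empty_batch_repeats_last_values(self):
        state = AccumulationState("bc", Kingdom.bacteria)
        update_accumulation(state, _profile({"a": 3, "b": 2}))
        update_accumulation(state, _profile({}))
        assert state.s_obs_history == [2, 2]
        assert state.reads_history == [5, 5]

    def test_disjoint_batches_are_additive(self):
        state = AccumulationState("bc", Kingdom.bacteria)
        update_accumulation(state, _profile({"a": 1, "b": 1, "c": 1}))
        update_accumulation(state, _profile({"d": 1, "e": 1}))
        assert state.s_obs_history == [3, 5]

    def test_final_state_is_order_independent(self, rng):
        batches = []
        for _ in range(6):
            species = {f"s{int(j)}": int(rng.integers(1, 5))
                       for j in rng.choice(20, size=rng.integers(1, 6), replace=False)}
            batches.append(species)
        orders = [list(range(6)), list(rng.permutation(6))]
        finals = []
        for order in orders:
            state = AccumulationState("bc", Kingdom.bacteria)
            for i in order:
                update_accumulation(state, _profile(batches[i]))
            finals.append(Counter(state.species_counts))
        assert finals[0] == finals[1]

    def test_kingdom_mismatch_rejected(self):
        state = AccumulationState("bc", Kingdom.fungi)
        with pytest.raises(ValueError):
            update_accumulation(state, _profile({"a": 1}))


def _state(s_obs, reads=None, chao=None, barcode="bc", kingdom=Kingdom.bacteria):
    state = AccumulationState(barcode, kingdom)
    state.s_obs_history = list(s_obs)
    state.chao1_history = list(chao if chao is not None else map(float, s_obs))
    state.reads_history = list(reads if reads is not None else [1000] * len(s_obs))
    return state


class TestIsSaturated:
    def test_zero_gain_is_saturated(self):
        assert is_saturated(_state([40, 40, 40, 40])) == SaturationStatus.saturated

    def test_growing_history_is_gaining(self):
        assert is_saturated(_state([10, 18, 30])) == SaturationStatus.gaining

    def test_few_reads_insufficient(self):
        state = _state([5, 5, 5], reads=[100, 200, 300])
        assert is_saturated(state) == SaturationStatus.insufficient_reads

    def test_chao_gain_blocks_saturation(self):
        state = _state([40, 40, 40], chao=[40.0, 44.0, 48.0])
        assert is_saturated(state) == SaturationStatus.gaining

    def test_simulated_accumulation_saturates_and_never_reverts(self, rng):
        """Fixed 50-species community streamed in 4,000-read batches: the
        status walks gaining -> saturated and is absorbed there."""
        probs = rng.dirichlet(np.ones(50) * 2)
        state = AccumulationState("bc", Kingdom.bacteria)
        params = SaturationParams()
        statuses = []
        for _ in range(12):
            draw = rng.multinomial(4000, probs)
            batch = {f"sp{i}": int(n) for i, n in enumerate(draw) if n > 0}
            update_accumulation(state, _profile(batch))
            statuses.append(is_saturated(state, params))
        assert statuses[0] != SaturationStatus.saturated
        assert SaturationStatus.saturated in statuses
        first = statuses.index(SaturationStatus.saturated)
        assert all(s == SaturationStatus.saturated for s in statuses[first:])


class TestStopRecommendation:
    def _plate(self, n_saturated, n_total):
        states = []
        for i in range(n_total):
            bc = f"barcode{i:02d}"
            hist = [40, 40, 40, 40] if i < n_saturated else [10, 18, 30]
            for kd in (Kingdom.bacteria, Kingdom.fungi):
                states.append(_state(hist, barcode=bc, kingdom=kd))
        return states, [f"barcode{i:02d}" for i in range(n_total)]

    def test_majority_arithmetic_47_of_93(self):
        states, eligible = self._plate(47, 93)
        decision = stop_recommendation(states, eligible_barcodes=eligible)
        assert decision.fraction_saturated == pytest.approx(47 / 93)
        assert decision.stop  # 0.5054 >= 0.5

    def test_46_of_93_does_not_stop(self):
        states, eligible = self._plate(46, 93)
        assert not stop_recommendation(states, eligible_barcodes=eligible).stop

    def test_all_insufficient_continues(self):
        states = [
            _state([3, 3, 3], reads=[50, 80, 90], barcode=f"b{i}") for i in range(4)
        ]
        decision = stop_recommendation(states, eligible_barcodes=[f"b{i}" for i in range(4)])
        assert not decision.stop
        assert decision.fraction_saturated == 0.0

    def test_unanimity_required_when_majority_frac_is_one(self):
        states, eligible = self._plate(9, 10)
        params = SaturationParams(majority_frac=1.0)
        assert not stop_recommendation(states, params, eligible).stop
        states, eligible = self._plate(10, 10)
        assert stop_recommendation(states, params, eligible).stop

    def test_both_kingdoms_required(self):
        bc = "barcode00"
        states = [
            _state([40, 40, 40, 40], barcode=bc, kingdom=Kingdom.bacteria),
            _state([10, 18, 30], barcode=bc, kingdom=Kingdom.fungi),
        ]
        decision = stop_recommendation(states, eligible_barcodes=[bc])
        assert decision.fraction_saturated == 0.0

    def test_least_accumulated_reported_ascending(self):
        states = [
            _state([40, 40, 40, 40], reads=[100 * (i + 1)] * 4, barcode=f"b{i}")
            for i in range(6)
        ]
        decision = stop_recommendation(
            states, eligible_barcodes=[f"b{i}" for i in range(6)], n_least=3
        )
        reads = [r for _, r in decision.least_accumulated]
        assert reads == sorted(reads) and len(reads) == 3
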