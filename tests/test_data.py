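import math

import numpy as np
import pandas as pd
import pytest

from choicebias.data import (ChoiceObservation, FormatError, LotShape, Lottery,
                             Problem, cpc18_compatible, expand_problem,
                             read_dataset, split_train_test, write_dataset)
from choicebias.synth import SynthConfig, sample_problem_space


class TestLottery:
    def test_merges_duplicates_and_sorts(self):
        lot = Lottery([5, 1, 5], [0.2, 0.5, 0.3])
        assert lot.outcomes == (1.0, 5.0)
        assert lot.probs == (0.5, 0.5)

    @pytest.mark.parametrize("outcomes,probs", [
        ([1, 2], [0.5, 0.6]),          # does not sum to 1
        ([1, 2], [1.2, -0.2]),         # outside [0, 1]
        ([np.inf], [1.0]),             # non-finite payoff
        ([], []),                      # empty support
    ])
    def test_rejects_invalid(self, outcomes, probs):
        with pytest.raises(ValueError):
            Lottery(outcomes, probs)

    def test_moments_match_direct_arithmetic(self, worked_lotteries):
        a, _ = worked_lotteries
        assert a.ev() == pytest.approx(0.05 * 12 + 0.05 * 14 + 0.9 * 96)
        mu = a.ev()
        var = 0.05 * (12 - mu) ** 2 + 0.05 * (14 - mu) ** 2 + 0.9 * (96 - mu) ** 2
        assert a.sd() == pytest.approx(math.sqrt(var))


class TestExpandProblem:
    def test_degenerate_shape_is_two_outcomes(self):
        p = Problem(id="x", ha=1, p_ha=1.0, la=0, hb=90, p_hb=0.05, lb=12)
        _, b = expand_problem(p)
        assert dict(zip(b.outcomes, b.probs)) == {90.0: pytest.approx(0.05),
                                                  12.0: pytest.approx(0.95)}

    def test_sure_thing_a(self):
        p = Problem(id="x", ha=50, p_ha=1.0, la=0, hb=1, p_hb=0.5, lb=0)
        a, _ = expand_problem(p)
        assert a.outcomes == (50.0,) and a.probs == (1.0,)

    def test_symmetric_expansion_mass_and_centre(self):
        p = Problem(id="x", ha=10, p_ha=0.5, la=0, hb=40, p_hb=0.6, lb=5,
                    lot_shape_b=LotShape.SYMM, lot_num_b=3)
        _, b = expand_problem(p)
        high = {o: pr for o, pr in zip(b.outcomes, b.probs) if o != 5.0}
        assert set(high) == {39.0, 40.0, 41.0}
        # binomial(2, 1/2) weights scaled by pHb, total mass = pHb
        assert sum(high.values()) == pytest.approx(0.6)
        assert high[40.0] == pytest.approx(0.3)
        assert sum(b.probs) == pytest.approx(1.0)

    @pytest.mark.parametrize("shape", [LotShape.R_SKEW, LotShape.L_SKEW])
    def test_skewed_expansion_mass_and_direction(self, shape):
        p = Problem(id="x", ha=10, p_ha=0.5, la=0, hb=40, p_hb=0.4, lb=1,
                    lot_shape_b=shape, lot_num_b=4)
        _, b = expand_problem(p)
        high = {o: pr for o, pr in zip(b.outcomes, b.probs) if o != 1.0}
        assert sum(high.values()) == pytest.approx(0.4)
        tail = max(high) if shape is LotShape.R_SKEW else min(high)
        assert abs(tail - 40.0) == pytest.approx(7.0)  # 2^3 - 1 spacing
        # probability decays toward the tail
        assert high[40.0] > high[tail]

    def test_invalid_shape_combination(self):
        with pytest.raises(FormatError):
            Problem(id="x", ha=1, p_ha=0.5, la=0, hb=1, p_hb=0.5, lb=0,
                    lot_shape_b=LotShape.SYMM, lot_num_b=4)
        with pytest.raises(FormatError):
            Problem(id="x", ha=1, p_ha=0.5, la=0, hb=1, p_hb=0.5, lb=0,
                    lot_num_b=3)  # shapeless with num > 1

    def test_expansion_always_valid(self):
        problems = sample_problem_space(SynthConfig(n_problems=200, seed=5))
        for p in problems:
            a, b = expand_problem(p)
            assert sum(a.probs) == pytest.approx(1.0)
            assert sum(b.probs) == pytest.approx(1.0)


class TestReadWrite:
    def test_round_trip_identity(self, paired_data, tmp_path):
        lab, _ = paired_data
        path = tmp_path / "lab.csv"
        write_dataset(lab, path)
        back = read_dataset(path, "canonical")
        assert back == lab

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"Ha": [1]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="missing columns"):
            read_dataset(path, "cpc15")

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_dataset(path, "canonical")

    def test_rates_validated_on_read(self, paired_data, tmp_path):
        lab, _ = paired_data
        frame = pd.read_csv(write_dataset(lab, tmp_path / "x.csv") or tmp_path / "x.csv")
        frame.loc[0, "b_rate"] = 1.7
        frame.to_csv(tmp_path / "x.csv", index=False)
        with pytest.raises(FormatError):
            read_dataset(tmp_path / "x.csv", "canonical")

    def test_cpc18_filter_drops_shaped_a(self):
        frame = pd.DataFrame({
            "LotShapeA": ["-", "Symm", "-"],
            "LotNumA": [1, 3, 1],
        })
        assert cpc18_compatible(frame).tolist() == [True, False, True]


class TestSplit:
    def test_partition_and_sizes(self, paired_data):
        lab, _ = paired_data
        train, test = split_train_test(lab, 0.8, seed=3)
        assert len(train) + len(test) == len(lab)
        train_ids = {o.problem.id for o in train}
        test_ids = {o.problem.id for o in test}
        assert not train_ids & test_ids
        n_problems = len(train_ids | test_ids)
        assert len(train_ids) == pytest.approx(0.8 * n_problems, abs=2)

    def test_deterministic_given_seed(self, paired_data):
        lab, _ = paired_data
        assert split_train_test(lab, 0.8, seed=9) == split_train_test(lab, 0.8, seed=9)
        other = split_train_test(lab, 0.8, seed=10)
        assert other != split_train_test(lab, 0.8, seed=9)

    def test_blocks_travel_together(self):
        obs = []
        for pid in range(6):
            for block in (1, 2):
                p = Problem(id=f"g{pid}", ha=10, p_ha=0.5, la=0,
                            hb=8, p_hb=0.6, lb=1, feedback=True, block=block)
                obs.append(ChoiceObservation(problem=p, n_participants=10, b_rate=0.5))
        train, test = split_train_test(obs, 0.5, seed=0)
        for side in (train, test):
            ids = [o.problem.id for o in side]
            assert all(ids.count(i) == 2 for i in set(ids))

    def test_too_few_problems(self, simple_problem):
        obs = [ChoiceObservation(problem=simple_problem, n_participants=5, b_rate=0.4)]
        with pytest.raises(ValueError):
            split_train_test(obs, 0.5, seed=0)
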