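"""Age-length keys and Isermann-Knight age assignment."""

import numpy as np
import pandas as pd
import pytest

import seawhip as sw

BIN5 = sw.LengthBinning(width_cm=5.0, origin_cm=0.0)


def make_key(p_rows, bins, ages, kind="observed", n=None):
    p = pd.DataFrame(p_rows, index=bins, columns=ages, dtype=float)
    n = pd.Series(n if n is not None else [10] * len(bins), index=bins)
    return sw.AgeLengthKey(p=p, n=n, binning=BIN5, kind=kind)


class TestObservedALK:
    def test_single_bin_even_split(self):
        key = sw.observed_alk([(12.0, 3), (13.0, 3), (11.0, 4), (14.0, 4)], BIN5)
        assert key.p.loc[10.0, 3] == 0.5
        assert key.p.loc[10.0, 4] == 0.5
        key.validate()

    def test_point_mass_rows(self):
        key = sw.observed_alk([(12.0, 5), (22.0, 5), (23.0, 5)], BIN5)
        occupied = key.p.dropna(how="all")
        assert (occupied[5] == 1.0).all()

    def test_hand_crosstab_three_bins_two_ages(self):
        # bin 10: 2x age3, 1x age4; bin 15: 1x age3, 3x age4; bin 20: 2x age4
        aged = [(11, 3), (12, 3), (13, 4), (16, 3), (17, 4), (18, 4), (19, 4),
                (21, 4), (24, 4)]
        key = sw.observed_alk(aged, BIN5)
        expect = np.array([[2 / 3, 1 / 3], [1 / 4, 3 / 4], [0.0, 1.0]])
        np.testing.assert_allclose(key.p.to_numpy(), expect)
        assert list(key.n) == [3, 4, 2]

    def test_intermediate_empty_bin_is_nan_not_zero(self):
        key = sw.observed_alk([(12.0, 3), (22.0, 4)], BIN5)
        assert key.p.loc[15.0].isna().all()
        assert key.n.loc[15.0] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sw.observed_alk([], BIN5)


class TestSmoothedALK:
    def test_null_limit_rows_equal_overall_proportions(self):
        # every bin has identical age composition -> fitted slope is exactly
        # zero and every predicted row equals the overall age proportions
        aged = []
        for b in [10, 20, 30, 40]:
            aged += [(b + 2.0, 4)] * 3 + [(b + 2.0, 7)] * 2 + [(b + 2.0, 9)] * 1
        key = sw.smoothed_alk(aged, sw.LengthBinning(width_cm=10.0))
        arr = key.p.to_numpy()
        np.testing.assert_allclose(arr, np.tile(arr[0], (4, 1)), atol=1e-6)
        np.testing.assert_allclose(arr[0], [0.5, 1 / 3, 1 / 6], atol=1e-5)
        key.validate()

    def test_separated_ages_modal_switch_monotone(self):
        rng = np.random.default_rng(0)
        lengths = np.concatenate([rng.uniform(5, 30, 50), rng.uniform(60, 85, 50)])
        ages = np.array([3] * 50 + [9] * 50)
        key = sw.smoothed_alk(zip(lengths, ages), BIN5)
        modal = key.p.idxmax(axis=1)
        assert modal.iloc[0] == 3 and modal.iloc[-1] == 9
        assert np.all(np.diff(key.p[9].to_numpy()) > -1e-9)
        key.validate()

    def test_vbgf_population_mean_age_nondecreasing_in_length(self, vbgf_truth):
        rng = np.random.default_rng(3)
        ages = np.array(list(sw.DEFAULT_AGE_DISTRIBUTION))
        probs = np.array(list(sw.DEFAULT_AGE_DISTRIBUTION.values()))
        a = rng.choice(ages, p=probs, size=500)
        lengths = sw.predict_length(vbgf_truth, a) + rng.normal(0, 5, 500)
        key = sw.smoothed_alk(zip(np.maximum(lengths, 1.0), a), BIN5)
        mean_age = (key.p * key.ages).sum(axis=1).to_numpy()
        assert np.all(np.diff(mean_age) > -1e-9)

    def test_fills_empty_bins(self):
        aged = [(12.0, 3), (13.0, 3), (32.0, 7), (33.0, 7), (22.0, 3), (23.0, 7)]
        key = sw.smoothed_alk(aged, BIN5)
        assert not key.p.loc[25.0].isna().any()  # no aged colony in [25, 30)
        key.validate()

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sw.smoothed_alk([(12.0, 3), (13.0, 3)], BIN5)  # one age
        with pytest.raises(ValueError):
            sw.smoothed_alk([(12.0, 3), (13.0, 4)], BIN5)  # one bin


class TestAssignAgesIK:
    def test_point_mass_bin(self):
        key = make_key([[1.0]], bins=[0.0], ages=[5])
        out = sw.assign_ages_ik([1.0] * 7, key, seed=0)
        assert (out["assigned_age"] == 5).all()
        assert (out["stage"] == "deterministic").all()

    def test_two_reachable_outcomes(self):
        key = make_key([[0.25, 0.75]], bins=[0.0], ages=[3, 4])
        seen = set()
        for seed in range(40):
            out = sw.assign_ages_ik([2.0] * 10, key, seed=seed)
            vc = out["assigned_age"].value_counts()
            seen.add((int(vc.get(3, 0)), int(vc.get(4, 0))))
            assert len(out) == 10
        assert seen <= {(3, 7), (2, 8)}
        assert len(seen) == 2  # both outcomes occur across seeds

    def test_top_bin_all_inclusive(self):
        key = make_key([[1.0, 0.0], [0.0, 1.0]], bins=[80.0, 85.0], ages=[9, 12])
        out = sw.assign_ages_ik([100.2], key, seed=1)
        assert out.loc[0, "bin_lower_cm"] == 85.0
        assert out.loc[0, "assigned_age"] == 12

    def test_missing_bin_errors_when_not_all_inclusive(self):
        binning = sw.LengthBinning(width_cm=5.0, last_bin_all_inclusive=False)
        p = pd.DataFrame([[1.0]], index=[10.0], columns=[4], dtype=float)
        key = sw.AgeLengthKey(p=p, n=pd.Series([5], index=[10.0]), binning=binning,
                              kind="observed")
        with pytest.raises(ValueError, match="no key row"):
            sw.assign_ages_ik([22.0], key, seed=0)

    def test_conservation_per_bin_and_overall(self):
        key = make_key(
            [[0.3, 0.5, 0.2], [0.1, 0.6, 0.3]], bins=[10.0, 15.0], ages=[3, 4, 5]
        )
        lengths = [11.0] * 13 + [17.0] * 9
        out = sw.assign_ages_ik(lengths, key, seed=2)
        assert len(out) == 22
        assert (out["bin_lower_cm"] == 10.0).sum() == 13
        assert (out["bin_lower_cm"] == 15.0).sum() == 9

    def test_deterministic_stage_never_over_allocates(self):
        key = make_key([[0.37, 0.63]], bins=[0.0], ages=[2, 6])
        n_l = 11
        out = sw.assign_ages_ik([1.0] * n_l, key, seed=3)
        det = out[out["stage"] == "deterministic"]["assigned_age"].value_counts()
        assert det.get(2, 0) <= np.floor(n_l * 0.37)
        assert det.get(6, 0) <= np.floor(n_l * 0.63)

    def test_expected_composition_matches_key(self):
        """Mean assigned composition over seeded replicates equals n_l * p."""
        p = np.array([0.22, 0.45, 0.33])
        key = make_key([p], bins=[0.0], ages=[3, 4, 5])
        n_l, reps = 10, 1000
        totals = np.zeros(3)
        rng = np.random.default_rng(99)
        for _ in range(reps):
            out = sw.assign_ages_ik([1.0] * n_l, key, seed=rng)
            vc = out["assigned_age"].value_counts()
            totals += [vc.get(a, 0) for a in (3, 4, 5)]
        mean_counts = totals / reps
        # only the single remainder unit is stochastic: se per age <= 0.5/sqrt(reps)
        se = 0.5 / np.sqrt(reps)
        np.testing.assert_allclose(mean_counts, n_l * p, atol=3 * se + 1e-9)

    def test_self_assignment_reproduces_age_totals_in_expectation(self):
        rng = np.random.default_rng(7)
        lengths = rng.uniform(10, 60, 80)
        ages = np.clip((lengths / 10).astype(int) + rng.integers(-1, 2, 80), 1, None)
        key = sw.observed_alk(zip(lengths, ages), BIN5)
        true_counts = pd.Series(ages).value_counts().sort_index()
        reps = 100
        acc = np.zeros(len(true_counts))
        seeds = np.random.default_rng(8)
        for _ in range(reps):
            out = sw.assign_ages_ik(lengths, key, seed=seeds)
            vc = out["assigned_age"].value_counts()
            acc += [vc.get(a, 0) for a in true_counts.index]
        # stochastic-remainder noise per bin is < 1; totals pool ~11 bins
        np.testing.assert_allclose(acc / reps, true_counts.to_numpy(), atol=0.5)
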