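"""Frequency computation, the depleted-mass correction and the OFF/t0
ratio normalization, checked against direct arithmetic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamscreen.normalize import (
    DEPLETION_THRESHOLD,
    NormalizationError,
    adjust_counts,
    correct_frequencies,
    correct_on_frequencies,
    find_depleted,
    normalize_time_series,
    to_frequencies,
)
from pamscreen.pams import ALL_PAMS

PAMS = list(ALL_PAMS)


def row(values) -> pd.Series:
    return pd.Series(values, index=PAMS[: len(values)], name="s")


def full_row(values) -> pd.Series:
    assert len(values) == 64
    return pd.Series(values, index=PAMS, name="s")


def midx(pairs):
    return pd.MultiIndex.from_tuples(pairs, names=["replicate", "time"])


class TestToFrequencies:
    def test_uniform_counts(self):
        counts = pd.DataFrame([[100] * 64], columns=PAMS)
        f = to_frequencies(counts)
        np.testing.assert_allclose(f.to_numpy(), 1 / 64)

    def test_small_example(self):
        counts = pd.DataFrame([[3, 1] + [0] * 62], columns=PAMS)
        f = to_frequencies(counts).iloc[0]
        assert f.iloc[0] == 0.75 and f.iloc[1] == 0.25 and f.iloc[2:].sum() == 0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(10, 64)), columns=PAMS)
        np.testing.assert_allclose(to_frequencies(counts).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_raises(self):
        counts = pd.DataFrame([[0] * 64], columns=PAMS, index=["bad_sample"])
        with pytest.raises(NormalizationError, match="bad_sample"):
            to_frequencies(counts)


class TestFindDepleted:
    def test_uniform_row_has_no_depletion(self):
        assert find_depleted(full_row([1 / 64] * 64)) == ()

    def test_single_low_pam_detected(self):
        values = [(1 - 0.004) / 63] * 64
        values[5] = 0.004  # < 1/128 by direct comparison
        assert find_depleted(full_row(values)) == (PAMS[5],)

    def test_degenerate_one_hot_row(self):
        values = [0.0] * 64
        values[0] = 1.0
        assert set(find_depleted(full_row(values))) == set(PAMS[1:])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.full(64, 0.5))
        lo = set(find_depleted(full_row(f), threshold=DEPLETION_THRESHOLD / 4))
        hi = set(find_depleted(full_row(f), threshold=DEPLETION_THRESHOLD))
        assert lo <= hi


class TestCorrectFrequencies:
    def test_no_depletion_is_identity_in_both_modes(self):
        f = full_row([1 / 64] * 64)
        for mode in ("multiply", "divide"):
            corrected, report = correct_frequencies(f, mode=mode)
            pd.testing.assert_series_equal(corrected, f)
            assert report.depleted == () and report.factor == 1.0

    def test_worked_example_both_modes(self):
        # two depleted PAMs at 0.004 (S = 0.008); a surviving PAM at 0.020
        values = [0.004, 0.004, 0.020] + [(1 - 0.028) / 61] * 61
        f = full_row(values)
        multiplied, _ = correct_frequencies(f, mode="multiply")
        divided, _ = correct_frequencies(f, mode="divide")
        assert multiplied.iloc[2] == pytest.approx(0.01984, abs=1e-12)
        assert divided.iloc[2] == pytest.approx(0.020 / 0.992, abs=1e-12)
        assert divided.iloc[2] == pytest.approx(0.0201613, abs=5e-8)

    def test_multiply_idempotent_when_no_new_crossing(self):
        values = [0.001, 0.002] + [(1 - 0.003) / 62] * 62
        f = full_row(values)
        once, r1 = correct_frequencies(f, mode="multiply")
        twice, r2 = correct_frequencies(once, mode="multiply")
        assert set(r1.depleted) == set(r2.depleted)
        # second pass rescales by the (tiny) already-shrunk depleted mass
        assert r2.depleted_mass == pytest.approx(r1.depleted_mass * r1.factor)

    def test_unit_depleted_mass_raises(self):
        # 63 ON PAMs are depleted and the control row concentrates at least
        # unit mass on them: the scale factor degenerates
        on = full_row([0.001] * 63 + [1 - 0.063])
        ref = full_row([0.017] * 63 + [0.0])
        with pytest.raises(NormalizationError):
            correct_frequencies(on, reference=ref)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.full(64, rng.uniform(0.05, 5.0)))
        fr = full_row(f)
        corrected, report = correct_frequencies(fr, mode="multiply")
        # independent element-wise oracle
        s = sum(v for v in f if v < 1 / 128)
        expected = [v * (1 - s) for v in f]
        np.testing.assert_allclose(corrected.to_numpy(), expected, atol=1e-15)
        assert report.depleted_mass == pytest.approx(s, abs=1e-15)


class TestAdjustCounts:
    def test_total_adjustment_halves_on(self):
        on = pd.DataFrame([[2 * 100_000 // 64] * 64], columns=PAMS, index=midx([(1, 0.0)]))
        off = pd.DataFrame([[100_000 // 64] * 64], columns=PAMS, index=midx([(1, 0.0)]))
        f = to_frequencies(on)
        adjusted = adjust_counts(on, off, f, f)
        np.testing.assert_allclose(adjusted.to_numpy(), off.to_numpy())

    def test_identical_samples_are_unchanged(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(500, 2000, size=(1, 64)), columns=PAMS, index=midx([(1, 0.0)])
        )
        f = to_frequencies(counts)
        adjusted = adjust_counts(counts, counts, f, f)
        np.testing.assert_allclose(adjusted.to_numpy(), counts.to_numpy())

    def test_missing_off_partner_raises(self):
        on = pd.DataFrame([[10] * 64], columns=PAMS, index=midx([(1, 0.0)]))
        off = pd.DataFrame([[10] * 64], columns=PAMS, index=midx([(2, 0.0)]))
        with pytest.raises(NormalizationError):
            adjust_counts(on, off, to_frequencies(on), to_frequencies(on))


class TestTimeSeries:
    def make_counts(self, on_rows, off_rows, times):
        idx = midx([(1, t) for t in times])
        on = pd.DataFrame(on_rows, columns=PAMS, index=idx)
        off = pd.DataFrame(off_rows, columns=PAMS, index=idx)
        return on, off

    def test_on_equals_off_gives_unit_ratio(self):
        rows = [[100] * 64, [100] * 64]
        on, off = self.make_counts(rows, rows, [0.0, 1.0])
        r = normalize_time_series(on, off)
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_halving_one_pam_frequency_gives_half_ratio(self):
        base = [128] * 64
        # PAM 0 loses half its frequency; PAM 1 absorbs the counts so the
        # sample total (and every other frequency) is unchanged
        shifted = [64, 192] + [128] * 62
        on, off = self.make_counts([base, shifted], [base, base], [0.0, 1.0])
        r = normalize_time_series(on, off, pseudocount=0.0)
        assert r.loc[(1, 1.0)].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert r.loc[(1, 1.0)].iloc[1] == pytest.approx(1.5, abs=1e-12)
        np.testing.assert_allclose(r.loc[(1, 1.0)].iloc[2:], 1.0, atol=1e-12)

    def test_r_at_t0_is_exactly_one(self):
        rng = np.random.default_rng(3)
        on, off = self.make_counts(
            [rng.integers(50, 150, 64) for _ in range(2)],
            [rng.integers(50, 150, 64) for _ in range(2)],
            [0.0, 1.0],
        )
        r = normalize_time_series(on, off)
        np.testing.assert_allclose(r.loc[(1, 0.0)].to_numpy(), 1.0, atol=0)

    def test_interfering_closed_form_recovered(self, scenario):
        # a planted interfering PAM decays as exp(-4 * (t - 1)); at t = 3 h
        # the ratio is exp(-8) -- indistinguishable from the sequencing-error
        # floor, so assert strong depletion rather than the exact value,
        # and check an intermediate PAM against its closed form.
        cfg = scenario["cfg"]
        counts = scenario["counts"]
        r = normalize_time_series(
            counts.xs("ON", level="condition"), counts.xs("OFF", level="condition")
        )
        mean_r = r.groupby(level="time").mean()
        assert mean_r.loc[3.0, "AAG"] < 0.01
        slow = "ACA"  # slowest planted intermediate
        expected = np.exp(-cfg.rate(slow) * (24.0 - cfg.induction_lag))
        assert mean_r.loc[24.0, slow] == pytest.approx(expected, rel=0.35)


class TestPipelineCorrection:
    def test_reference_summed_multiply_restores_stable_diagonal(self, scenario):
        cfg = scenario["cfg"]
        counts = scenario["counts"]
        f_on = to_frequencies(counts.xs("ON", level="condition"))
        f_off = to_frequencies(counts.xs("OFF", level="condition"))
        corrected, _ = correct_on_frequencies(f_on, f_off)
        stable = [p for p, g in cfg.pam_groups.items() if g == "stable"]
        ratio = corrected[stable] / f_off.loc[corrected.index, stable]
        n = cfg.reads_per_sample
        c = n / 64
        bound = 3 * np.sqrt(2 / c)
        for t in cfg.time_points:
            med = ratio.xs(t, level="time").stack().median()
            assert abs(med - 1) < bound, f"t={t}: {med}"
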