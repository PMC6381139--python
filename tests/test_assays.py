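"""OSER statistics, Tukey HSD, histogram overlap, gating, phase lifetime."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import studentized_range

from fpchar.assays import (
    fsc_gate,
    lifetime_to_phase,
    oser_summary,
    overlap_percent,
    phase_lifetime,
    tukey_hsd,
)
from fpchar.core import OserRecord
from fpchar.synth import gen_oser


def _records(counts):
    return [OserRecord(f"c{i}", "fp", c) for i, c in enumerate(counts)]


class TestOserSummary:
    def test_all_zero(self):
        s = oser_summary(_records([0, 0, 0, 0]))
        assert s.mean_whorls_per_cell == 0.0
        assert s.frac_cells_with_whorl == 0.0
        assert s.ci95_mean == (0.0, 0.0) and s.ci95_frac == (0.0, 0.0)

    def test_all_one(self):
        s = oser_summary(_records([1, 1, 1]))
        assert s.mean_whorls_per_cell == 1.0
        assert s.frac_cells_with_whorl == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            oser_summary([])

    def test_ci_brackets_estimate(self):
        s = oser_summary(gen_oser(0.3, 1.5, 500, seed=1))
        assert s.ci95_frac[0] <= s.frac_cells_with_whorl <= s.ci95_frac[1]
        assert s.ci95_mean[0] <= s.mean_whorls_per_cell <= s.ci95_mean[1]


class TestTukeyHSD:
    def test_identical_groups_not_significant(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        table = tukey_hsd(g)
        assert not table["significant"].any()
        assert table["q"].iloc[0] == pytest.approx(0.0)

    def test_separated_groups_significant(self):
        g = {"a": [1.0, 1.01, 0.99], "b": [10.0, 10.01, 9.99]}
        assert tukey_hsd(g)["significant"].all()

    def test_q_matches_direct_formula(self):
        """Balanced 3-group case against the from-scratch studentized-range
        computation."""
        g = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([2.0, 3.0, 4.0, 5.0]),
            "c": np.array([5.0, 6.0, 7.0, 9.0]),
        }
        table = tukey_hsd(g, alpha=0.01)
        means = {k: float(np.mean(v)) for k, v in g.items()}
        msw = sum(float(np.sum((v - means[k]) ** 2)) for k, v in g.items()) / (12 - 3)
        for row in table.itertuples():
            se = math.sqrt(msw / 2.0 * (1 / 4 + 1 / 4))
            q_expected = abs(means[row.group2] - means[row.group1]) / se
            assert row.q == pytest.approx(q_expected, abs=1e-10)
        crit = studentized_range.ppf(0.99, 3, 9)
        assert table["q_crit"].iloc[0] == pytest.approx(crit)

    def test_agreement_with_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(5)
        g = {
            "a": rng.normal(0.0, 1.0, 12),
            "b": rng.normal(0.5, 1.0, 15),
            "c": rng.normal(3.0, 1.0, 9),
        }
        ours = tukey_hsd(g, alpha=0.05)
        data = np.concatenate(list(g.values()))
        labels = sum(([k] * len(v) for k, v in g.items()), [])
        ref = pairwise_tukeyhsd(data, labels, alpha=0.05)
        np.testing.assert_array_equal(
            ours["significant"].to_numpy(), np.asarray(ref.reject)
        )

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        g = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10)}
        shifted = {k: v + 100.0 for k, v in g.items()}
        a = tukey_hsd(g)
        b = tukey_hsd(shifted)
        np.testing.assert_array_equal(
            a["significant"].to_numpy(), b["significant"].to_numpy()
        )

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": [1.0], "b": [1.0, 2.0]})


class TestOverlap:
    def test_identical_samples_full_overlap(self):
        x = np.random.default_rng(1).lognormal(size=500)
        assert overlap_percent(x, x) == pytest.approx(100.0)

    def test_disjoint_samples_zero(self):
        assert overlap_percent([1.0, 1.1, 1.2], [100.0, 101.0]) == pytest.approx(0.0)

    def test_half_overlap_construction(self):
        # masses (1/2, 1/2, 0) vs (0, 1/2, 1/2) on shared bins -> 50%
        a = np.concatenate([np.full(50, 1.5), np.full(50, 15.0)])
        b = np.concatenate([np.full(50, 15.0), np.full(50, 150.0)])
        assert overlap_percent(a, b, n_bins=3) == pytest.approx(50.0)

    @given(st.integers(0, 5))
    def test_symmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.lognormal(0.0, 0.5, 200)
        b = rng.lognormal(0.5, 0.5, 300)
        ab = overlap_percent(a, b)
        assert ab == pytest.approx(overlap_percent(b, a))
        assert ab == pytest.approx(overlap_percent(a * 7.5, b * 7.5), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            overlap_percent([], [1.0])


class TestPhaseLifetime:
    def test_zero_phase_zero_lifetime(self):
        assert phase_lifetime(0.0, 75.1e6).lifetime_ns == 0.0

    def test_quarter_pi_at_instrument_frequency(self):
        # tan(pi/4) = 1 at 75.1 MHz modulation: 1/(2 pi f) = 2.119 ns
        m = phase_lifetime(math.pi / 4, 75.1e6)
        assert m.lifetime_ns == pytest.approx(1e9 / (2 * math.pi * 75.1e6))
        assert m.lifetime_ns == pytest.approx(2.119, abs=1e-3)

    def test_round_trip_identity(self):
        phase = lifetime_to_phase(4.0, 75.1e6)
        assert phase == pytest.approx(math.atan(2 * math.pi * 0.0751 * 4.0))
        back = phase_lifetime(phase, 75.1e6)
        assert back.lifetime_ns == pytest.approx(4.0, abs=1e-12)

    @given(st.floats(0.0, 1.5))
    def test_inverse_composition(self, phase):
        tau = phase_lifetime(phase, 75.1e6).lifetime_ns
        assert lifetime_to_phase(tau, 75.1e6) == pytest.approx(phase, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            phase_lifetime(math.pi / 2, 75.1e6)


class TestFscGate:
    def test_all_below_threshold_empty(self):
        assert fsc_gate([(1000.0, 5.0), (2000.0, 6.0)]) == []

    def test_zero_threshold_identity(self):
        events = [(1000.0, 5.0), (90000.0, 6.0)]
        assert fsc_gate(events, threshold=0.0) == [5.0, 6.0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        events = list(zip(rng.uniform(0, 2e5, 500), rng.lognormal(size=500)))
        ours = fsc_gate(events)
        ref = [fl for fsc, fl in events if fsc >= 80000.0]
        assert ours == ref
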