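"""Joint-frequency tables, wind-ratio roses, consolidation, annualization."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radonrecon.meteorology import (
    DIRECTIONS_16,
    OCTETS,
    JointFrequencyTable,
    MetValidationError,
    WindRatioRose,
    annualize,
    consolidate_16_to_8,
    load_met_tables,
    scale_speeds,
    stability_adjusted_frequency,
    weighted_wind_velocity,
    wind_ratio_rose,
    write_met_tables,
)

from conftest import make_delta_table, make_random_table, make_uniform_table


def brute_force_ratio(table, d_index):
    """Triple-loop oracle for the wind ratio of one direction."""
    total = 0.0
    for si in range(6):
        for qi in range(6):
            total += (
                table.class_freq[si]
                * table.cond_freq[si, d_index, qi]
                / table.speed_midpoints[qi]
            )
    return total


class TestStabilityAdjustedFrequency:
    def test_product_rule(self):
        # h_F = 0.5 via a two-class table, g_{1,N|F} = 0.2
        h = np.array([0.5, 0, 0, 0, 0, 0.5])
        g = np.full((6, 16, 6), 1 / 96)
        g[5] = 0.0
        g[5, 0, 0] = 0.2
        g[5, 1, 0] = 0.8
        t = JointFrequencyTable(month=1, class_freq=h, cond_freq=g)
        assert stability_adjusted_frequency(t, "F", "N", 1) == pytest.approx(0.1)

    def test_zero_class_frequency_zeroes_all_cells(self):
        t = make_delta_table(s=5, d=0, q=0)
        for d in DIRECTIONS_16:
            for q in range(1, 7):
                assert stability_adjusted_frequency(t, "A", d, q) == 0.0

    def test_uniform_symmetry(self, uniform_table):
        vals = [
            stability_adjusted_frequency(uniform_table, s, d, q)
            for s in range(6)
            for d in range(16)
            for q in range(1, 7)
        ]
        assert np.allclose(vals, 1 / 576)


class TestWindRatioRose:
    def test_all_mass_slowest_class(self):
        rose = wind_ratio_rose(make_delta_table(s=5, d=0, q=0))
        assert rose.ratio("N") == pytest.approx(1.0)
        assert rose.total() == pytest.approx(1.0)

    def test_all_mass_fastest_class(self):
        rose = wind_ratio_rose(make_delta_table(s=5, d=0, q=5))
        assert rose.ratio("N") == pytest.approx(1 / 11)
        assert sum(rose.ratio(d) for d in DIRECTIONS_16 if d != "N") == 0.0

    def test_uniform_table_matches_brute_force(self, uniform_table):
        rose = wind_ratio_rose(uniform_table)
        expected = brute_force_ratio(uniform_table, 0)
        assert np.allclose(rose.ratios, expected)

    def test_random_table_matches_brute_force(self):
        t = make_random_table(np.random.default_rng(7))
        rose = wind_ratio_rose(t)
        for di in range(16):
            assert rose.ratios[di] == pytest.approx(brute_force_ratio(t, di))

    def test_linearity_in_frequency_table(self):
        """Mixing two tables' joint frequencies mixes their roses."""
        rng = np.random.default_rng(8)
        t1, t2 = make_random_table(rng), make_random_table(rng)
        lam = 0.3
        h = lam * t1.class_freq + (1 - lam) * t2.class_freq
        f = lam * t1.joint() + (1 - lam) * t2.joint()
        mixed = JointFrequencyTable(month=1, class_freq=h, cond_freq=f / h[:, None, None])
        expected = lam * wind_ratio_rose(t1).by_stability + (1 - lam) * wind_ratio_rose(
            t2
        ).by_stability
        assert np.allclose(wind_ratio_rose(mixed).by_stability, expected)

    def test_speed_scaling_inverse_law(self):
        t = make_random_table(np.random.default_rng(9))
        k = 2.5
        scaled = wind_ratio_rose(scale_speeds(t, k))
        assert np.allclose(scaled.ratios, wind_ratio_rose(t).ratios / k)


class TestConsolidation:
    def test_splitting_rule(self):
        by_stab = np.zeros((6, 16))
        by_stab[0, DIRECTIONS_16.index("N")] = 0.10
        by_stab[0, DIRECTIONS_16.index("NNE")] = 0.04
        by_stab[0, DIRECTIONS_16.index("NNW")] = 0.02
        rose8 = consolidate_16_to_8(WindRatioRose(DIRECTIONS_16, by_stab))
        assert rose8.ratio("N") == pytest.approx(0.13)
        assert rose8.ratio("NE") == pytest.approx(0.02)
        assert rose8.ratio("NW") == pytest.approx(0.01)

    def test_all_zero(self):
        rose8 = consolidate_16_to_8(WindRatioRose(DIRECTIONS_16, np.zeros((6, 16))))
        assert rose8.total() == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_total_conserved(self, seed):
        rose16 = wind_ratio_rose(make_random_table(np.random.default_rng(seed)))
        rose8 = consolidate_16_to_8(rose16)
        assert rose8.total() == pytest.approx(rose16.total(), abs=1e-12)
        assert rose8.directions == OCTETS


class TestAnnualize:
    def test_idempotent_on_identical_months(self):
        rose = wind_ratio_rose(make_random_table(np.random.default_rng(3)))
        out = annualize([rose] * 12)
        assert np.allclose(out.by_stability, rose.by_stability)

    def test_single_nonzero_month(self):
        by_stab = np.zeros((6, 16))
        by_stab[0, 0] = 1.2
        hot = WindRatioRose(DIRECTIONS_16, by_stab)
        cold = WindRatioRose(DIRECTIONS_16, np.zeros((6, 16)))
        out = annualize([hot] + [cold] * 11)
        assert out.ratio("N") == pytest.approx(0.1)

    def test_matches_elementwise_mean(self):
        rng = np.random.default_rng(4)
        roses = [wind_ratio_rose(make_random_table(rng, m)) for m in range(1, 13)]
        out = annualize(roses)
        expected = sum(r.by_stability for r in roses) / 12
        assert np.allclose(out.by_stability, expected)

    def test_rejects_wrong_month_count(self):
        rose = wind_ratio_rose(make_uniform_table())
        with pytest.raises(ValueError):
            annualize([rose] * 11)


class TestWeightedWindVelocity:
    def test_all_mass_slowest(self):
        _, overall = weighted_wind_velocity(make_delta_table(s=5, d=0, q=0))
        assert overall == pytest.approx(1.0)

    def test_all_mass_fastest(self):
        _, overall = weighted_wind_velocity(make_delta_table(s=5, d=0, q=5))
        assert overall == pytest.approx(11.0)

    def test_matches_brute_force(self):
        t = make_random_table(np.random.default_rng(5))
        per_dir, overall = weighted_wind_velocity(t)
        brute = 0.0
        for si in range(6):
            for di in range(16):
                for qi in range(6):
                    brute += (
                        t.class_freq[si] * t.cond_freq[si, di, qi] * t.speed_midpoints[qi]
                    )
        assert overall == pytest.approx(brute)
        assert per_dir.sum() == pytest.approx(brute)

    def test_speed_scaling_direct_law(self):
        t = make_random_table(np.random.default_rng(6))
        _, base = weighted_wind_velocity(t)
        _, scaled = weighted_wind_velocity(scale_speeds(t, 3.0))
        assert scaled == pytest.approx(3.0 * base)


class TestValidation:
    def test_bad_class_normalization_rejected(self):
        with pytest.raises(MetValidationError):
            JointFrequencyTable(
                month=1, class_freq=np.full(6, 0.2), cond_freq=np.full((6, 16, 6), 1 / 96)
            )

    def test_bad_conditional_normalization_rejected(self):
        g = np.full((6, 16, 6), 1 / 96)
        g[2] *= 1.5
        with pytest.raises(MetValidationError, match="C"):
            JointFrequencyTable(month=1, class_freq=np.full(6, 1 / 6), cond_freq=g)

    def test_negative_frequency_rejected(self):
        g = np.full((6, 16, 6), 1 / 96)
        g[0, 0, 0] = -g[0, 0, 0]
        g[0, 0, 1] += 2 / 96  # keep the sum at 1
        with pytest.raises(MetValidationError):
            JointFrequencyTable(month=1, class_freq=np.full(6, 1 / 6), cond_freq=g)


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, met12_seeded):
        cond, cls = tmp_path / "met.csv", tmp_path / "met_class.csv"
        write_met_tables(met12_seeded, cond, cls)
        again = load_met_tables(cond, cls)
        for a, b in zip(met12_seeded, again):
            assert a.month == b.month
            assert np.allclose(a.class_freq, b.class_freq)
            assert np.allclose(a.cond_freq, b.cond_freq)
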