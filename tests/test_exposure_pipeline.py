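"""Matrix assembly, per-subject exposure, summaries, exceedance, footprint."""
from datetime import date

import numpy as np
import pytest

from radonrecon.dispersion import CalibrationParams, DispersionConfig, concentration
from radonrecon.exposure_pipeline import (
    build_matrix,
    cohort_summary,
    compute_cohort_exposures,
    exceedance_count,
    population_and_footprint,
    sector_ranking,
    subject_annual_exposure,
    subject_exposure,
    subject_mean_exposure,
)
from radonrecon.residential_history import CleanedResidence, Subject
from radonrecon.sector_grid import Sector, SectorGrid, reciprocal_direction
from radonrecon.source_term import EmissionEvent, EmissionTimeline


def make_subject(sid, *residences):
    return Subject(
        subject_id=sid,
        dob=date(1930, 1, 1),
        residences=[
            CleanedResidence(subject_id=sid, sector_id=s, start=a, end=b)
            for s, a, b in residences
        ],
    )


@pytest.fixture(scope="module")
def matrix(grid, timeline, met12_seeded):
    return build_matrix(grid, timeline, met12_seeded)


class TestBuildMatrix:
    def test_zero_timeline_gives_zero_matrix(self, grid, met12_seeded):
        silent = EmissionTimeline(
            [EmissionEvent("none", (1952, 7), (1988, 12), 0.0, 0.0, 0.0)]
        )
        m = build_matrix(grid, silent, met12_seeded)
        assert (m.monthly == 0).all()

    def test_nearer_ring_strictly_larger(self, matrix, grid):
        by_octet_ring = {(s.octet, s.ring): s.id for s in grid.sectors.values()}
        for octet in ("N", "NE", "E", "SE", "S", "SW", "W", "NW"):
            near, far = by_octet_ring[(octet, 1)], by_octet_ring[(octet, 2)]
            for year in range(1953, 1989):
                assert matrix.annual_value(near, year) > matrix.annual_value(far, year)

    def test_year_ratio_equals_source_rate_ratio(self, matrix, timeline):
        expected = timeline.annual_rate(1965) / timeline.annual_rate(1985)
        for sid in matrix.sector_ids:
            ratio = matrix.annual_value(sid, 1965) / matrix.annual_value(sid, 1985)
            assert ratio == pytest.approx(expected, abs=1e-9)

    def test_annual_is_mean_of_monthly(self, matrix):
        vals = [matrix.monthly_value("B03", 1970, m) for m in range(1, 13)]
        assert matrix.annual_value("B03", 1970) == pytest.approx(np.mean(vals))

    def test_cell_matches_scalar_concentration(self, matrix, grid, timeline, met12_seeded):
        """The vectorized grid agrees with the one-receptor plume formula."""
        from radonrecon.exposure_pipeline import monthly_wind_ratio_stack
        from radonrecon.meteorology import OCTETS

        R8 = monthly_wind_ratio_stack(met12_seeded)
        for sid, year, month in [("B03", 1965, 6), ("H41", 1980, 2), ("H05", 1953, 7)]:
            octet, dist = grid.receptor_geometry(sid)
            upwind = OCTETS.index(reciprocal_direction(octet))
            res = concentration(
                CalibrationParams(),
                DispersionConfig(),
                R8[month - 1, :, upwind],
                timeline.monthly_rate(year, month),
                dist,
            )
            assert matrix.monthly_value(sid, year, month) == pytest.approx(res.value)

    def test_end_to_end_linearity_in_source(self, grid, timeline, met12_seeded, matrix):
        scaled_tl = EmissionTimeline(
            [
                EmissionEvent(e.label, e.start, e.end, 3 * e.rate_median,
                              3 * e.rate_p05, 3 * e.rate_p95)
                for e in timeline.events
            ]
        )
        m3 = build_matrix(grid, scaled_tl, met12_seeded)
        assert np.allclose(m3.monthly, 3 * matrix.monthly)


class TestSubjectExposure:
    def test_full_year_single_sector(self, matrix):
        s = make_subject("a", ("B03", date(1965, 1, 1), date(1965, 12, 31)))
        assert subject_annual_exposure(matrix, s, 1965) == pytest.approx(
            matrix.annual_value("B03", 1965)
        )

    def test_split_year_two_sectors(self, matrix):
        s = make_subject(
            "a",
            ("B03", date(1965, 1, 1), date(1965, 6, 30)),
            ("H02", date(1965, 7, 1), date(1965, 12, 31)),
        )
        expected = np.mean(
            [matrix.monthly_value("B03", 1965, m) for m in range(1, 7)]
            + [matrix.monthly_value("H02", 1965, m) for m in range(7, 13)]
        )
        assert subject_annual_exposure(matrix, s, 1965) == pytest.approx(expected)

    def test_not_resident_contributes_nothing(self, matrix):
        s = make_subject("a", ("B03", date(1965, 1, 1), date(1965, 12, 31)))
        exp = subject_exposure(matrix, s)
        assert 1970 not in exp.annual
        assert subject_annual_exposure(matrix, s, 1970) == 0.0

    def test_mean_weighted_example(self):
        # 5 years at 2.0 and 7 years at 1.0 -> 17/12
        annual = {y: 2.0 for y in range(1960, 1965)} | {y: 1.0 for y in range(1965, 1972)}
        weights = {y: 1.0 for y in annual}
        assert subject_mean_exposure(annual, weights) == pytest.approx(17 / 12)

    def test_mean_constant_series(self):
        annual = {1960: 1.3, 1961: 1.3}
        assert subject_mean_exposure(annual, {1960: 1.0, 1961: 0.5}) == pytest.approx(1.3)

    def test_mean_within_annual_range(self, matrix):
        s = make_subject("a", ("B03", date(1958, 3, 1), date(1979, 10, 31)))
        exp = subject_exposure(matrix, s)
        assert min(exp.annual.values()) <= exp.mean <= max(exp.annual.values())

    def test_zero_resident_time_excluded(self, matrix):
        s = make_subject("a", ("B03", date(1995, 1, 1), date(1996, 1, 1)))
        cohort = compute_cohort_exposures(matrix, [s])
        assert cohort.subjects == []
        assert cohort.n_excluded_no_residence == 1


@pytest.fixture(scope="module")
def cohort(matrix):
    subjects = [
        make_subject(f"s{i}", ("B03", date(1955 + i, 1, 1), date(1960 + 2 * i, 12, 31)))
        for i in range(10)
    ] + [make_subject("far", ("H41", date(1960, 1, 1), date(1980, 12, 31)))]
    return compute_cohort_exposures(matrix, subjects)


class TestExceedance:
    def test_threshold_zero_counts_everyone(self, cohort):
        count, frac = exceedance_count(cohort, 0.0, "any_year")
        assert count == len(cohort.subjects)
        assert frac == 1.0

    def test_threshold_above_max_counts_none(self, cohort):
        top = max(max(s.annual.values()) for s in cohort.subjects)
        assert exceedance_count(cohort, top + 1, "any_year") == (0, 0.0)

    @pytest.mark.parametrize("mode", ["any_year", "overall_mean"])
    def test_matches_brute_force_scan(self, cohort, mode):
        threshold = float(np.median(cohort.means()))
        brute = 0
        for s in cohort.subjects:
            if mode == "any_year":
                brute += any(v > threshold for v in s.annual.values())
            else:
                brute += s.mean > threshold
        assert exceedance_count(cohort, threshold, mode)[0] == brute

    def test_unknown_mode_rejected(self, cohort):
        with pytest.raises(ValueError):
            exceedance_count(cohort, 4.0, "monthly")


class TestCohortSummary:
    def test_identical_subjects(self, matrix):
        subjects = [
            make_subject(f"s{i}", ("B03", date(1960, 1, 1), date(1960, 12, 31)))
            for i in range(4)
        ]
        stats = cohort_summary(compute_cohort_exposures(matrix, subjects))
        v = matrix.annual_value("B03", 1960)
        assert stats["arithmetic_mean"] == pytest.approx(v)
        assert stats["median"] == pytest.approx(v)
        assert stats["geometric_mean"] == pytest.approx(v)
        assert stats["arithmetic_sd"] == pytest.approx(0.0)

    def test_two_value_textbook_case(self):
        from radonrecon.exposure_pipeline import CohortExposures, SubjectExposure

        cohort = CohortExposures(
            subjects=[
                SubjectExposure("a", {1960: 1.0}, {1960: 1.0}, 1.0, 1.0),
                SubjectExposure("b", {1960: 4.0}, {1960: 1.0}, 4.0, 1.0),
            ]
        )
        stats = cohort_summary(cohort)
        assert stats["arithmetic_mean"] == pytest.approx(2.5)
        assert stats["geometric_mean"] == pytest.approx(2.0)
        assert stats["max_annual"] == pytest.approx(4.0)


class TestSectorRanking:
    def test_single_sector_grid(self, timeline, met12_seeded):
        g = SectorGrid([Sector("B03", "NE", 1)])
        m = build_matrix(g, timeline, met12_seeded)
        ranking = sector_ranking(m, g, k=10)
        assert list(ranking["sector_id"]) == ["B03"]

    def test_nearer_ring_ranks_first(self, matrix, grid):
        ranking = sector_ranking(matrix, grid, k=100)
        pos = {sid: i for i, sid in enumerate(ranking["sector_id"])}
        assert pos["B03"] < pos["B08"] < pos["B16"]  # NE rings 1 < 2 < 3

    def test_max_mean_ratio_constant_across_sectors(self, grid, timeline):
        """With one met table held fixed across months the matrix factorizes
        into spatial × temporal, so Maximum/Mean is identical for every
        sector."""
        from conftest import make_random_table

        fixed = [make_random_table(np.random.default_rng(21), m) for m in [1]] * 12
        fixed = [
            type(fixed[0])(month=m, class_freq=fixed[0].class_freq,
                           cond_freq=fixed[0].cond_freq)
            for m in range(1, 13)
        ]
        m = build_matrix(grid, timeline, fixed)
        ranking = sector_ranking(m, grid, k=100)
        ratios = ranking["max_pci_per_l"] / ranking["mean_pci_per_l"]
        assert np.allclose(ratios, ratios.iloc[0], atol=1e-9)


class TestPopulationAndFootprint:
    def test_single_subject_population(self, matrix, grid):
        s = make_subject("a", ("B03", date(1960, 1, 1), date(1965, 12, 31)))
        out = population_and_footprint([s], grid, matrix)
        pop = out["population_by_year"].set_index("year")["population"]
        assert (pop.loc[1960:1965] == 1).all()
        assert pop.drop(range(1960, 1966)).sum() == 0
        decades = out["population_by_sector_decade"]
        assert set(decades["decade"]) == {1960}
        assert decades["population"].sum() == 1

    def test_empty_cohort(self, matrix, grid):
        out = population_and_footprint([], grid, matrix)
        assert out["population_by_year"]["population"].sum() == 0
        assert out["population_by_sector_decade"].empty

    def test_footprint_matches_brute_force_tally(self, matrix, grid):
        out = population_and_footprint([], grid, matrix)
        foot = out["octet_mean_exposure"].set_index("octet")["mean_sector_pci_per_l"]
        for octet in ("NE", "SW"):
            ids = [s.id for s in grid.sectors.values() if s.octet == octet]
            expected = np.mean([matrix.annual.mean(axis=1)[matrix.sector_ids.index(i)] for i in ids])
            assert foot[octet] == pytest.approx(expected)
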