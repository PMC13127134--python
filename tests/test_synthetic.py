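"""Synthetic generator reproducibility and packaged-table integrity."""
import numpy as np
import pytest

import frailtysim as fs
from frailtysim.structure import AGE_BANDS, ValidationError
from frailtysim.synthetic import gen_entry_schedule


class TestGeneratorReproducibility:
    def test_same_seed_gives_identical_artifacts(self):
        cfg = fs.GeneratorConfig(seed=42)
        p1, p2 = fs.gen_parameter_set(cfg), fs.gen_parameter_set(cfg)
        np.testing.assert_array_equal(p1.transition, p2.transition)
        np.testing.assert_array_equal(p1.mortality, p2.mortality)
        np.testing.assert_array_equal(p1.entry_mix, p2.entry_mix)
        r1, r2 = fs.gen_service_rates(cfg), fs.gen_service_rates(cfg)
        np.testing.assert_array_equal(r1.rates, r2.rates)
        np.testing.assert_array_equal(fs.gen_unit_costs(cfg).costs,
                                      fs.gen_unit_costs(cfg).costs)

    def test_degenerate_ranges_give_exact_values(self):
        cfg = fs.GeneratorConfig(seed=0, fit_mild_range=(0.07, 0.07),
                                 age_gradient=False)
        params = fs.gen_parameter_set(cfg)
        np.testing.assert_array_equal(params.transition[:, 0], 0.07)

    def test_draws_stay_within_declared_ranges(self):
        for seed in range(300):
            cfg = fs.GeneratorConfig(seed=seed)
            p = fs.gen_parameter_set(cfg)
            lo, hi = cfg.fit_mild_range
            assert np.all((p.transition[:, 0] >= lo) & (p.transition[:, 0] <= hi))
            lo, hi = cfg.mild_moderate_range
            assert np.all((p.transition[:, 1] >= lo) & (p.transition[:, 1] <= hi))
            for b, (mlo, mhi) in enumerate(cfg.mortality_band_ranges):
                assert p.mortality[:, 0].min() >= cfg.mortality_band_ranges[0][0]
            assert abs(p.entry_mix.sum() - 1.0) < 1e-12

    def test_age_gradient_orders_rates_across_bands(self):
        for seed in range(50):
            p = fs.gen_parameter_set(fs.GeneratorConfig(seed=seed))
            assert np.all(np.diff(p.transition, axis=0) >= 0)
            assert np.all(np.diff(p.mortality, axis=0) >= 0)


class TestInitialStocks:
    def test_stocks_are_total_times_mix(self):
        cfg = fs.GeneratorConfig(seed=0)
        stocks = fs.gen_initial_stocks(cfg)
        assert stocks.total() == pytest.approx(cfg.total_population, rel=1e-9)
        np.testing.assert_allclose(
            stocks.counts, cfg.total_population * cfg.initial_mix)

    def test_configured_frail_mass_yields_expected_count(self):
        """A mix with 70.2% frail mass on the published 2025 total gives
        16 234 633 frail persons (+-1 person of rounding)."""
        mix = np.zeros((4, 4))
        mix[0, 0] = 0.298
        mix[0, 1] = 0.702
        cfg = fs.GeneratorConfig(seed=0, total_population=23_126_258,
                                 initial_mix=mix)
        stocks = fs.gen_initial_stocks(cfg)
        assert stocks.frail_total() == pytest.approx(16_234_633, abs=1.0)

    def test_single_stratum_mass(self):
        mix = np.zeros((4, 4))
        mix[2, 3] = 1.0
        stocks = fs.gen_initial_stocks(
            fs.GeneratorConfig(seed=0, total_population=100.0, initial_mix=mix))
        assert stocks.get("75-84", "severe") == 100.0
        assert stocks.total() == 100.0

    def test_zero_total_gives_zero_stocks(self):
        stocks = fs.gen_initial_stocks(
            fs.GeneratorConfig(seed=0, total_population=0.0))
        assert stocks.total() == 0.0

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValidationError):
            fs.GeneratorConfig(seed=0, initial_mix=np.full((4, 4), 0.1))


class TestMakeTruth:
    def test_entry_schedule_covers_simulated_years(self):
        cfg = fs.GeneratorConfig(seed=5)
        sched = gen_entry_schedule(cfg, 2025, 2039)
        assert sched.covers(2025, 2039)
        lo, hi = cfg.entrants_range
        assert np.all((sched.values >= lo) & (sched.values <= hi))

    def test_synthetic_prevalence_plateaus_in_target_regime(self, truth):
        """Default generator magnitudes produce a high-prevalence,
        slowly-plateauing frailty regime over a 16-year horizon."""
        prev = [fs.prevalence(sv).frail_fraction
                for sv in truth.trajectory.stocks]
        assert 0.60 <= prev[0] <= 0.80
        assert 0.65 <= prev[-1] <= 0.85
        assert abs(prev[-1] - prev[-2]) < abs(prev[1] - prev[0]) + 1e-9


class TestFixtureTables:
    def test_incidence_table_2025_row_as_printed(self, fixtures):
        row = fixtures.incidence.loc[2025]
        assert tuple(row[list(AGE_BANDS) + ["overall"]]) == (
            400_200, 160_300, 105_400, 31_100, 696_900)

    def test_contacts_2025_primary_row_as_printed(self, fixtures):
        row = fixtures.contacts.loc[2025]
        assert (row["primary_fit"], row["primary_frail"],
                row["primary_total"]) == (37.4, 225.1, 262.5)

    def test_costs_2040_frail_total_as_printed(self, fixtures):
        assert fixtures.costs.loc[2040, "all_frail"] == 55_745.5

    def test_column_totals_match_printed_totals(self, fixtures):
        """Summed annual values reproduce the printed column totals at
        printed precision; the 65-74 total is carried exactly as printed
        (9 persons above the rounded annual sum, a pre-rounding total)."""
        sums = fixtures.incidence.sum(axis=0)
        totals = fixtures.incidence_totals
        for col in ("50-64", "75-84", "85+", "overall"):
            assert sums[col] == totals[col]
        assert totals["65-74"] == 2_509_209
        assert sums["65-74"] == 2_509_200

    def test_row_sums_match_overall_at_printed_precision(self, fixtures):
        """Band values were rounded to 100 before printing, so a row of four
        can differ from the printed overall by at most half a unit each."""
        bands = fixtures.incidence[list(AGE_BANDS)].sum(axis=1)
        assert (bands - fixtures.incidence["overall"]).abs().max() <= 200

    def test_contact_and_cost_rows_are_additive_as_printed(self, fixtures):
        t2, t3 = fixtures.contacts, fixtures.costs
        assert (t2["primary_fit"] + t2["primary_frail"]
                - t2["primary_total"]).abs().max() <= 0.1 + 1e-9
        assert (t3["primary_total"] + t3["secondary_total"]
                - t3["all_total"]).abs().max() <= 0.1 + 1e-9

    def test_scalars_have_provenance(self, fixtures):
        assert (fixtures.scalar_sources.str.len() > 0).all()
        assert fixtures.scalars["population_2025"] == 23_126_258

    def test_checksum_mismatch_detected(self, monkeypatch):
        from frailtysim import synthetic
        monkeypatch.setitem(synthetic._FIXTURE_SHA256,
                            "table1_incidence.csv", "0" * 64)
        with pytest.raises(ValidationError):
            synthetic._read_fixture("table1_incidence.csv")
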