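"""Population engine: stepping arithmetic, affine-map oracle, invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import frailtysim as fs
from frailtysim.engine import build_affine_map, capped_outflow_rates
from frailtysim.structure import ValidationError

from conftest import random_parameter_set, random_stocks


def zero_params():
    return fs.ParameterSet.zeros()


class TestStep:
    def test_zero_rates_zero_entrants_leave_stocks_unchanged(self):
        stocks = random_stocks(0)
        new, flows = fs.step(stocks, zero_params(), 0.0)
        np.testing.assert_array_equal(new.counts, stocks.counts)
        assert new.year == stocks.year + 1
        assert flows.total_deaths() == 0.0
        assert flows.incidence.sum() == 0.0

    def test_single_stratum_incidence_arithmetic(self):
        counts = np.zeros((4, 4))
        counts[0, 0] = 1000.0
        params = zero_params()
        tr = params.transition.copy()
        tr[0, 0] = 0.1
        params = params.with_(transition=tr)
        new, flows = fs.step(fs.StockVector(counts, 2025), params, 0.0)
        assert new.get("50-64", "fit") == pytest.approx(900.0)
        assert new.get("50-64", "mild") == pytest.approx(100.0)
        assert flows.incidence[0] == pytest.approx(100.0)

    def test_entrants_added_per_entry_mix_after_flows(self):
        params = zero_params().with_(entry_mix=np.array([0.5, 0.3, 0.15, 0.05]))
        new, flows = fs.step(fs.StockVector(np.zeros((4, 4)), 2025), params, 1000.0)
        np.testing.assert_allclose(new.counts[0], [500, 300, 150, 50])
        np.testing.assert_allclose(flows.entries, [500, 300, 150, 50])

    def test_rejects_negative_entrants_and_nan(self):
        stocks = random_stocks(1)
        with pytest.raises(ValidationError):
            fs.step(stocks, zero_params(), -1.0)
        with pytest.raises(ValidationError):
            fs.step(stocks, zero_params(), float("nan"))

    def test_rejects_negative_or_nan_stocks(self):
        with pytest.raises(ValidationError):
            fs.StockVector(np.full((4, 4), -1.0), 2025)
        counts = np.ones((4, 4))
        counts[2, 2] = np.nan
        with pytest.raises(ValidationError):
            fs.StockVector(counts, 2025)


class TestAffineMap:
    def test_zero_rates_give_identity_and_zero_entry_into_frail(self):
        M, template = build_affine_map(zero_params())
        np.testing.assert_array_equal(M, np.eye(16))
        assert template[0] == 1.0 and template[1:].sum() == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_column_outflow_matches_rates(self, seed):
        params = random_parameter_set(seed)
        M, _ = build_affine_map(params)
        death, transit, ageing = capped_outflow_rates(params)
        # column i sums to 1 - mortality of stratum i (transitions and
        # ageing reappear in other rows)
        col_sums = M.sum(axis=0).reshape(4, 4)
        np.testing.assert_allclose(col_sums, 1.0 - death, atol=1e-12)

    def test_frailty_block_triangular_no_recovery(self):
        for seed in range(20):
            M, _ = build_affine_map(random_parameter_set(seed))
            for b in range(4):
                block = M[b * 4:(b + 1) * 4, b * 4:(b + 1) * 4]
                assert np.all(np.triu(block, 1) == 0.0), \
                    "flow to a less frail state"
            # off-band entries only on the ageing superdiagonal (j -> j+4)
            for i in range(16):
                for j in range(16):
                    if i // 4 != j // 4 and i != j + 4:
                        assert M[i, j] == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_of_run_and_matrix_iteration(self, seed):
        """run() equals the iterated affine map elementwise (1e-9 relative)."""
        params = random_parameter_set(seed)
        initial = random_stocks(seed)
        entries = fs.EntrySchedule.constant(2025, 2039, 5e5)
        traj = fs.run(initial, params, entries, 2025, 2040)
        M, template = build_affine_map(params)
        x = initial.flat()
        for year in range(2025, 2040):
            x = M @ x + entries.entrants(year) * template
            np.testing.assert_allclose(
                traj.stock(year + 1).flat(), x, rtol=1e-9, atol=1e-9)


class TestRun:
    def test_zero_length_horizon_returns_only_initial_stocks(self):
        initial = random_stocks(3)
        entries = fs.EntrySchedule.constant(2025, 2039, 0.0)
        traj = fs.run(initial, zero_params(), entries, 2025, 2025)
        assert traj.years == [2025]
        assert traj.flows == ()
        np.testing.assert_array_equal(traj.stock(2025).counts, initial.counts)

    def test_population_constant_without_mortality_or_entrants(self):
        params = random_parameter_set(11).with_(mortality=np.zeros((4, 4)))
        initial = random_stocks(11)
        entries = fs.EntrySchedule.constant(2025, 2039, 0.0)
        traj = fs.run(initial, params, entries, 2025, 2040)
        totals = traj.total_series()
        np.testing.assert_allclose(totals, totals.iloc[0], rtol=1e-9)

    @pytest.mark.parametrize("seed", range(15))
    def test_conservation_total_change_equals_entrants_minus_deaths(self, seed):
        params = random_parameter_set(seed)
        initial = random_stocks(seed)
        entries = fs.EntrySchedule.constant(2025, 2039, 3e5)
        traj = fs.run(initial, params, entries, 2025, 2040)
        for sv, flow in zip(traj.stocks[:-1], traj.flows):
            expected = sv.total() - flow.total_deaths() + flow.total_entries()
            nxt = traj.stock(sv.year + 1).total()
            assert nxt == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 5, 10, 15])
    def test_nonnegative_even_when_rates_sum_above_one(self, seed):
        """Capping keeps every stock and flow non-negative."""
        rng = np.random.default_rng(seed)
        params = fs.ParameterSet(
            transition=rng.uniform(0.3, 1.0, (4, 3)),
            mortality=rng.uniform(0.3, 1.0, (4, 4)),
            ageing=rng.uniform(0.3, 1.0, 3),
            entry_mix=np.array([1.0, 0, 0, 0]),
        )
        traj = fs.run(random_stocks(seed), params,
                      fs.EntrySchedule.constant(2025, 2039, 1e5), 2025, 2040)
        assert all(np.all(sv.counts >= 0) for sv in traj.stocks)
        for fl in traj.flows:
            assert np.all(fl.deaths >= 0) and np.all(fl.incidence >= 0)
            # deaths cannot exceed the start-of-year stock of the stratum
            start = traj.stock(fl.year).counts
            assert np.all(fl.deaths <= start + 1e-9)

    def test_deaths_capped_at_stock(self):
        params = zero_params().with_(mortality=np.full((4, 4), 1.0))
        stocks = random_stocks(2)
        new, flows = fs.step(stocks, params, 0.0)
        np.testing.assert_allclose(flows.deaths, stocks.counts)
        assert new.total() == pytest.approx(0.0, abs=1e-9)

    def test_monotone_frailty_ordering(self):
        """Raising one transition rate never lowers the downstream frail
        stock in any year.

        Holds whenever outflow capping is inactive; under capping a higher
        transition rate also rescales the stratum's mortality and ageing,
        so monotonicity is only claimed for sub-unit outflow sums.
        """
        for seed in range(8):
            params = fs.gen_parameter_set(fs.GeneratorConfig(seed=seed))
            initial = random_stocks(seed)
            entries = fs.EntrySchedule.constant(2025, 2039, 2e5)
            base = fs.run(initial, params, entries, 2025, 2040)
            rng = np.random.default_rng(seed)
            b, k = int(rng.integers(0, 4)), int(rng.integers(0, 3))
            tr = params.transition.copy()
            tr[b, k] = min(tr[b, k] + 0.1, 1.0)
            up = fs.run(initial, params.with_(transition=tr), entries,
                        2025, 2040)
            for year in base.years:
                assert (up.stock(year).counts[:, k + 1:].sum()
                        >= base.stock(year).counts[:, k + 1:].sum() - 1e-6)

    def test_horizon_schedule_mismatch_raises(self):
        entries = fs.EntrySchedule.constant(2025, 2030, 1e5)
        with pytest.raises(ValidationError):
            fs.run(random_stocks(0), zero_params(), entries, 2025, 2040)

    def test_run_is_deterministic(self):
        params = random_parameter_set(4)
        initial = random_stocks(4)
        entries = fs.EntrySchedule.constant(2025, 2039, 4e5)
        a = fs.run(initial, params, entries, 2025, 2040)
        b = fs.run(initial, params, entries, 2025, 2040)
        for y in a.years:
            np.testing.assert_array_equal(a.stock(y).counts, b.stock(y).counts)


class TestDerivedTables:
    def test_annual_incidence_is_fit_mild_flow_with_totals(self, truth):
        inc = fs.annual_incidence(truth.trajectory)
        no_total = inc.drop(index="Total")
        # flows recorded by the ledger match the table for stepped years
        for flow in truth.trajectory.flows:
            np.testing.assert_allclose(
                no_total.loc[flow.year, list(fs.AGE_BANDS)].to_numpy(float),
                flow.incidence, rtol=1e-12)
        np.testing.assert_allclose(
            no_total["Overall"],
            no_total[list(fs.AGE_BANDS)].sum(axis=1), rtol=1e-12)
        np.testing.assert_allclose(inc.loc["Total"], no_total.sum(axis=0),
                                   rtol=1e-12)

    def test_zero_fit_mild_rates_give_zero_incidence(self):
        traj = fs.run(random_stocks(9), zero_params(),
                      fs.EntrySchedule.constant(2025, 2039, 0.0), 2025, 2040)
        assert fs.annual_incidence(traj).to_numpy().sum() == 0.0

    def test_prevalence_of_published_2025_and_2040_counts(self):
        # printed frail/total pairs reproduce the printed prevalences at 1 dp
        p25 = fs.prevalence(_stocks_with(frail=16_228_687, total=23_126_258))
        assert round(100 * p25.frail_fraction, 1) == 70.2
        p40 = fs.prevalence(_stocks_with(frail=18_269_340, total=24_021_710))
        assert round(100 * p40.frail_fraction, 1) == 76.1

    def test_prevalence_all_fit_is_zero(self):
        counts = np.zeros((4, 4))
        counts[:, 0] = 100.0
        assert fs.prevalence(fs.StockVector(counts, 2025)).frail_fraction == 0.0

    def test_prevalence_of_empty_population_raises(self):
        with pytest.raises(ValidationError):
            fs.prevalence(fs.StockVector(np.zeros((4, 4)), 2025))


def _stocks_with(frail: float, total: float) -> fs.StockVector:
    counts = np.zeros((4, 4))
    counts[0, 0] = total - frail
    counts[0, 1] = frail
    return fs.StockVector(counts, 2025)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_property_conservation_and_nonnegativity(seed):
    """For any valid rate set, one step conserves persons up to deaths and
    entrants and never produces a negative stock."""
    params = random_parameter_set(seed)
    stocks = random_stocks(seed)
    new, flows = fs.step(stocks, params, 1e4)
    assert np.all(new.counts >= 0)
    assert new.total() == pytest.approx(
        stocks.total() - flows.total_deaths() + flows.total_entries(),
        rel=1e-9)
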