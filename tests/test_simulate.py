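"""Monte Carlo engine: correctness, conservation, convergence, sensitivity."""

import numpy as np
import pytest

from dredgecarbon.imputation import Log10MassModel
from dredgecarbon.records import HarmonisedEvent, Industry, MassProvenance, SedimentType
from dredgecarbon.simulate import (
    MT_KG,
    SimulationConfig,
    aggregate_country_to_shelf,
    aggregate_ports_to_nation,
    carbon_mass,
    convergence_study,
    estimates_to_dataframe,
    run_simulation,
    sensitivity_sediment_proportions,
)
from dredgecarbon.toc import EmpiricalTocDistribution


def _ev(rid, country="GB", year=2000, mass=1e9, industry=Industry.PORT_DREDGING,
        sed=SedimentType.UNKNOWN, site="", year_end=None, impute=False):
    return HarmonisedEvent(
        record_id=rid, industry=industry, country=country, year=year,
        year_end=year if year_end is None else year_end,
        mass_kg=None if impute else mass, needs_imputation=impute,
        sediment_type=sed,
        mass_provenance=None if impute else MassProvenance.REPORTED_MASS,
        site=site,
    )


def _dists(coastal_vals, **extra):
    dists = {"coastal": EmpiricalTocDistribution("coastal", np.asarray(coastal_vals, dtype=float))}
    for label, vals in extra.items():
        dists[label] = EmpiricalTocDistribution(label, np.asarray(vals, dtype=float))
    return dists


class TestCarbonMass:
    @pytest.mark.parametrize(
        "mass,toc,expected",
        [(1000, 1.78, 17.8), (12345.0, 0.0, 0.0), (1016, 100.0, 1016.0)],
    )
    def test_examples(self, mass, toc, expected):
        assert carbon_mass(mass, toc) == pytest.approx(expected)

    def test_out_of_range_toc_rejected(self):
        with pytest.raises(ValueError):
            carbon_mass(1.0, 101.0)
        with pytest.raises(ValueError):
            carbon_mass(1.0, -0.1)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            carbon_mass(-1.0, 1.0)


class TestRunSimulation:
    def test_degenerate_distribution_collapses_band(self):
        """A single-value pool removes all stochasticity: sd = 0, p5 = p95 = mean."""
        ests = run_simulation([_ev("a")], _dists([2.0]), config=SimulationConfig(n_runs=500, seed=3))
        (est,) = ests
        assert est.mean_kgc == pytest.approx(2e7)
        assert est.sd_kgc == 0.0
        assert est.p_low_kgc == est.p_high_kgc == est.mean_kgc
        assert est.mean_mt == pytest.approx(0.02)

    def test_grand_mean_matches_analytic_expectation(self):
        """E[total carbon] = sum(mass) x mean(pool)/100 (CLT oracle)."""
        rng = np.random.default_rng(8)
        pool = rng.lognormal(0.3, 0.7, size=400)
        events = [_ev(f"e{i}", mass=m) for i, m in enumerate([1e9, 3e9, 5e8])]
        cfg = SimulationConfig(n_runs=4000, seed=12)
        ests = run_simulation(events, _dists(pool), config=cfg)
        total_mean = sum(e.mean_kgc for e in ests)
        masses = np.array([1e9, 3e9, 5e8])
        expected = masses.sum() * pool.mean() / 100.0
        se = np.sqrt((masses**2).sum()) * pool.std() / 100.0 / np.sqrt(cfg.n_runs)
        assert total_mean == pytest.approx(expected, abs=3 * se)

    def test_seed_determinism_bit_exact(self):
        pool = np.linspace(0.1, 5.0, 97)
        events = [_ev(f"e{i}", mass=1e8 * (i + 1)) for i in range(4)]
        cfg = SimulationConfig(n_runs=300, seed=99)
        a = run_simulation(events, _dists(pool), config=cfg)
        b = run_simulation(events, _dists(pool), config=cfg)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.run_totals, eb.run_totals)

    def test_linearity_in_mass(self):
        """Doubling every event mass doubles mean and percentiles exactly."""
        pool = np.linspace(0.1, 5.0, 50)
        cfg = SimulationConfig(n_runs=400, seed=21)
        one = run_simulation([_ev("a", mass=1e9)], _dists(pool), config=cfg)[0]
        two = run_simulation([_ev("a", mass=2e9)], _dists(pool), config=cfg)[0]
        assert two.mean_kgc == pytest.approx(2 * one.mean_kgc, rel=1e-12)
        assert two.p_low_kgc == pytest.approx(2 * one.p_low_kgc, rel=1e-12)
        assert two.p_high_kgc == pytest.approx(2 * one.p_high_kgc, rel=1e-12)

    def test_run_totals_within_pool_bounds(self):
        pool = np.array([0.5, 1.0, 4.0])
        events = [_ev(f"e{i}", mass=1e9) for i in range(3)]
        ests = run_simulation(events, _dists(pool), config=SimulationConfig(n_runs=500, seed=2))
        total_mass = 3e9
        lo = total_mass * pool.min() / 100.0
        hi = total_mass * pool.max() / 100.0
        for est in ests:
            assert est.run_totals.min() >= lo / 3 - 1e-9  # per-group bound
            assert est.run_totals.max() <= hi + 1e-9

    def test_aggregate_events_use_their_sediment_pool(self):
        dists = _dists([10.0], sand=[1.0], coarse=[2.0], mixed=[3.0], combined=[4.0])
        events = [
            _ev("s", industry=Industry.AGGREGATE, sed=SedimentType.SAND, mass=1e9),
            _ev("u", industry=Industry.AGGREGATE, sed=SedimentType.UNKNOWN, mass=1e9, country="FR"),
        ]
        ests = run_simulation(events, dists, config=SimulationConfig(n_runs=10, seed=0))
        by_country = {e.country: e for e in ests}
        assert by_country["GB"].mean_kgc == pytest.approx(1e9 * 1.0 / 100)  # sand pool
        assert by_country["FR"].mean_kgc == pytest.approx(1e9 * 4.0 / 100)  # combined pool

    def test_unresolvable_event_names_record(self):
        events = [_ev("orphan", industry=Industry.AGGREGATE, sed=SedimentType.SAND)]
        with pytest.raises(ValueError, match="orphan"):
            run_simulation(events, _dists([1.0]))

    def test_imputation_needs_model(self):
        with pytest.raises(ValueError, match="mass model"):
            run_simulation([_ev("x", impute=True)], _dists([1.0]))

    def test_imputed_event_draws_from_mass_model(self):
        """With sigma = 0 the imputed mass is 10**mu exactly, so a degenerate
        pool makes the whole estimate deterministic."""
        model = Log10MassModel(mu=7.0, sigma=0.0, n=10)
        est = run_simulation(
            [_ev("h", impute=True, site="port1", year=1883, year_end=1903)],
            _dists([2.0]), mass_model=model, config=SimulationConfig(n_runs=50, seed=1),
        )[0]
        assert est.scope_type == "port"
        assert est.n_years == 21
        assert est.mean_kgc == pytest.approx(1e7 * 2.0 / 100)
        assert est.sd_kgc == 0.0

    def test_fix_imputed_masses_freezes_the_draw(self):
        model = Log10MassModel(mu=7.0, sigma=0.5, n=10)
        cfg = SimulationConfig(n_runs=200, seed=5, fix_imputed_masses=True)
        est = run_simulation([_ev("h", impute=True)], _dists([2.0]), model, cfg)[0]
        # one frozen mass, degenerate pool: spread is zero up to summation ulps
        assert est.sd_kgc == pytest.approx(0.0, abs=1e-12 * est.mean_kgc)

    def test_empty_event_set(self):
        assert run_simulation([], _dists([1.0])) == []


class TestAggregation:
    def test_shelf_is_exact_sum_of_countries(self):
        pool = np.linspace(0.2, 3.0, 40)
        events = [_ev(f"e{i}", country=c, mass=1e9) for i, c in enumerate(["GB", "DK", "NL"])]
        cfg = SimulationConfig(n_runs=300, seed=4)
        countries = run_simulation(events, _dists(pool), config=cfg)
        (shelf,) = aggregate_country_to_shelf(countries, cfg)
        assert np.array_equal(shelf.run_totals, sum(e.run_totals for e in countries))
        assert shelf.mean_kgc == pytest.approx(sum(e.mean_kgc for e in countries), rel=1e-12)

    def test_degenerate_country_totals_add(self):
        cfg = SimulationConfig(n_runs=20, seed=0)
        events = [
            _ev("a", country="GB", mass=1e9),
            _ev("b", country="DK", mass=2e9),
        ]
        ests = run_simulation(events, _dists([100.0]), config=cfg)
        (shelf,) = aggregate_country_to_shelf(ests, cfg)
        assert shelf.mean_mt == pytest.approx(3.0)  # 1 + 2 Mt at 100% TOC

    def test_country_reproducible_in_isolation(self):
        """A country simulated alone gives bit-identical run totals to its
        slice of the joint shelf run (per-scope substreams)."""
        pool = np.linspace(0.2, 3.0, 40)
        cfg = SimulationConfig(n_runs=200, seed=17)
        joint = run_simulation(
            [_ev("a", country="GB"), _ev("b", country="DK")], _dists(pool), config=cfg
        )
        alone = run_simulation([_ev("a", country="GB")], _dists(pool), config=cfg)
        gb_joint = next(e for e in joint if e.country == "GB")
        assert np.array_equal(gb_joint.run_totals, alone[0].run_totals)

    def test_nation_is_exact_sum_of_ports(self):
        cfg = SimulationConfig(n_runs=100, seed=6)
        events = [_ev(f"p{i}", site=f"port{i}", mass=1e7) for i in range(3)]
        ports = run_simulation(events, _dists([100.0]), config=cfg)
        (nation,) = aggregate_ports_to_nation(ports, cfg)
        assert nation.scope_type == "nation"
        assert nation.mean_mt == pytest.approx(0.03)
        assert np.array_equal(nation.run_totals, sum(p.run_totals for p in ports))

    def test_single_port_nation_identity(self):
        cfg = SimulationConfig(n_runs=100, seed=6)
        pool = np.linspace(0.5, 2.0, 10)
        (port,) = run_simulation([_ev("p", site="port0")], _dists(pool), config=cfg)
        (nation,) = aggregate_ports_to_nation([port], cfg)
        assert np.array_equal(nation.run_totals, port.run_totals)
        assert nation.p_low_kgc == port.p_low_kgc
        assert nation.p_high_kgc == port.p_high_kgc

    def test_nation_band_subadditive_vs_port_bands(self):
        """p95 of the summed runs never exceeds the sum of port p95s
        (aligned-run quantile subadditivity, checked empirically)."""
        cfg = SimulationConfig(n_runs=2000, seed=31)
        pool = np.random.default_rng(0).lognormal(0.5, 0.8, 200)
        events = [_ev(f"p{i}", site=f"port{i}", mass=1e8 * (i + 1)) for i in range(4)]
        ports = run_simulation(events, _dists(pool), config=cfg)
        (nation,) = aggregate_ports_to_nation(ports, cfg)
        assert nation.p_high_kgc <= sum(p.p_high_kgc for p in ports) + 1e-9

    def test_mismatched_n_runs_rejected(self):
        a = run_simulation([_ev("a", site="p1")], _dists([1.0]), config=SimulationConfig(n_runs=10, seed=0))
        b = run_simulation([_ev("b", site="p2")], _dists([1.0]), config=SimulationConfig(n_runs=20, seed=0))
        with pytest.raises(ValueError, match="n_runs"):
            aggregate_ports_to_nation(a + b)


class TestDrawScope:
    def test_per_year_total_widens_band(self):
        """Sharing one %TOC draw across a year's events removes averaging
        over events, so the band is at least as wide."""
        pool = np.random.default_rng(1).lognormal(0.5, 0.8, 300)
        events = [_ev(f"e{i}", mass=1e9) for i in range(8)]
        per_rec = run_simulation(events, _dists(pool),
                                 config=SimulationConfig(n_runs=3000, seed=9))[0]
        per_year = run_simulation(events, _dists(pool),
                                  config=SimulationConfig(n_runs=3000, seed=9,
                                                          draw_scope="per_year_total"))[0]
        assert per_year.sd_kgc > per_rec.sd_kgc
        assert per_year.mean_kgc == pytest.approx(per_rec.mean_kgc, rel=0.1)


class TestConvergence:
    def test_degenerate_pool_has_zero_spread_everywhere(self):
        events = [_ev("a")]
        table, summary = convergence_study(events, _dists([2.0]),
                                           run_grid=[50, 100], n_iterations=5, seed=1)
        assert len(table) == 10
        assert (summary["inter_iteration_sd"] == 0).all()
        assert summary["stabilised"].all()

    def test_spread_shrinks_like_sqrt_runs(self):
        """Inter-iteration SD scales ~ 1/sqrt(runs): a 100x run increase
        should shrink it by ~10x (allow 3x slack either way)."""
        pool = np.random.default_rng(2).lognormal(0.5, 0.8, 200)
        events = [_ev(f"e{i}", mass=1e9) for i in range(3)]
        table, summary = convergence_study(events, _dists(pool),
                                           run_grid=[100, 10000], n_iterations=10, seed=3)
        sd = summary.set_index("runs")["inter_iteration_sd"]
        ratio = sd[100] / sd[10000]
        assert 10 / 3 < ratio < 10 * 3

    def test_grid_shape_contract(self):
        events = [_ev("a")]
        table, summary = convergence_study(events, _dists([1.0, 2.0]),
                                           run_grid=[100, 500, 1000, 5000, 10000],
                                           n_iterations=10, seed=0)
        assert len(table) == 50
        assert list(summary["runs"]) == [100, 500, 1000, 5000, 10000]

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            convergence_study([_ev("a")], _dists([1.0]), run_grid=[500, 100])


class TestSensitivity:
    def _pools(self):
        rng = np.random.default_rng(5)
        return {
            "sand": EmpiricalTocDistribution("sand", rng.lognormal(-0.7, 1.0, 500)),
            "coarse": EmpiricalTocDistribution("coarse", rng.lognormal(-0.4, 1.0, 300)),
            "mixed": EmpiricalTocDistribution("mixed", rng.lognormal(-0.1, 1.0, 200)),
        }

    def test_pure_sand_equals_single_pool_simulation(self):
        dists = self._pools()
        cfg = SimulationConfig(n_runs=3000, seed=7)
        df = sensitivity_sediment_proportions(1e9, dists, [(1.0, 0.0, 0.0)], cfg)
        expected = 1e9 * dists["sand"].values.mean() / 100.0
        se = 1e9 * dists["sand"].values.std() / 100.0 / np.sqrt(cfg.n_runs)
        assert df["mean_kgc"].iloc[0] == pytest.approx(expected, abs=3 * se)

    def test_mean_monotone_between_endpoints(self):
        """With mean(sand) < mean(coarse), shifting weight from sand to
        coarse raises the estimate monotonically (mixture-mean oracle)."""
        dists = self._pools()
        grid = [(1.0 - t, t, 0.0) for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
        df = sensitivity_sediment_proportions(
            1e9, dists, grid, SimulationConfig(n_runs=20000, seed=13)
        )
        means = df["mean_kgc"].to_numpy()
        assert dists["sand"].values.mean() < dists["coarse"].values.mean()
        assert np.all(np.diff(means) > 0)

    def test_study_proportions_match_mixture_mean(self):
        """(0.53, 0.46, 0.01) reproduces the closed-form mixture expectation
        within Monte Carlo error."""
        dists = self._pools()
        cfg = SimulationConfig(n_runs=20000, seed=19)
        df = sensitivity_sediment_proportions(1e9, dists, [(0.53, 0.46, 0.01)], cfg)
        w = dict(zip(("sand", "coarse", "mixed"), (0.53, 0.46, 0.01)))
        expected = 1e9 * sum(w[c] * dists[c].values.mean() for c in w) / 100.0
        var = sum((1e9 * w[c] / 100.0) ** 2 * dists[c].values.var() for c in w)
        se = np.sqrt(var / cfg.n_runs)
        assert df["mean_kgc"].iloc[0] == pytest.approx(expected, abs=3 * se)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sensitivity_sediment_proportions(1e9, self._pools(), [(0.5, 0.4, 0.0)])


class TestResultsTable:
    def test_dataframe_units_and_columns(self):
        est = run_simulation([_ev("a", mass=1e9)], _dists([2.0]),
                             config=SimulationConfig(n_runs=10, seed=0))
        df = estimates_to_dataframe(est, seed=0)
        assert list(df.columns) == [
            "industry", "scope_type", "scope_id", "country", "year", "year_end",
            "mean_Mt", "sd_Mt", "p5_Mt", "p95_Mt", "n_runs", "seed",
        ]
        assert df["mean_Mt"].iloc[0] == pytest.approx(0.02)
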