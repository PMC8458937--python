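import numpy as np
import pytest

import densescreen as ds
from densescreen.sensitivity import (
    BracketError,
    Distribution,
    _signed_ratio,
    default_distributions,
)


class TestTornado:
    def test_empty_ranges_give_empty_list(self, params, rates):
        assert ds.one_way_tornado(params, {}, rates) == []

    def test_degenerate_range_has_zero_span(self, params, rates):
        entries = ds.one_way_tornado(
            params, {"cost_xm": (params.cost_xm, params.cost_xm)}, rates
        )
        assert entries[0].span == 0.0

    def test_range_must_bracket_base(self, params, rates):
        with pytest.raises(ValueError):
            ds.one_way_tornado(params, {"cost_mrm": (400.0, 500.0)}, rates)

    def test_invalid_range_rejected(self, params, rates):
        with pytest.raises(ds.ValidationError):
            ds.one_way_tornado(params, {"sens_mrm": (0.9, 1.2)}, rates)

    def test_order_invariance_and_sorting(self, params, rates):
        ranges = ds.default_tornado_ranges(params)
        fwd = ds.one_way_tornado(params, ranges, rates)
        rev = ds.one_way_tornado(params, dict(reversed(list(ranges.items()))), rates)
        assert [e.parameter for e in fwd] == [e.parameter for e in rev]
        spans = [e.span for e in fwd]
        assert spans == sorted(spans, reverse=True)

    def test_mrm_cost_drives_the_icer_and_mrm_sensitivity_does_not(
        self, params, rates
    ):
        """The examination cost of MRM has the widest bar; MRM sensitivity
        is among the narrowest."""
        entries = ds.one_way_tornado(params, ds.default_tornado_ranges(params), rates)
        names = [e.parameter for e in entries]
        spans = {e.parameter: e.span for e in entries}
        assert names[0] == "cost_mrm"
        assert names.index("sens_mrm") >= len(names) // 2
        assert spans["sens_mrm"] < 0.2 * spans["cost_mrm"]


class TestTwoWaySurface:
    def test_single_point_matches_base_ratio(self, params, rates):
        surf = ds.two_way_cost_specificity(
            params, [params.cost_mrm], [params.spec_mrm_later], rates
        )
        assert surf.iloc[0, 0] == pytest.approx(_signed_ratio(params, rates, None))

    def test_specificity_sweep_strictly_decreasing(self, params, rates):
        surf = ds.two_way_cost_specificity(
            params, [params.cost_mrm], np.arange(0.92, 0.9901, 0.01), rates
        )
        row = surf.iloc[0].to_numpy()
        assert np.all(np.diff(row) < 0)

    def test_invalid_grids_rejected(self, params, rates):
        with pytest.raises(ValueError):
            ds.two_way_cost_specificity(params, [-5.0], [0.95], rates)
        with pytest.raises(ValueError):
            ds.two_way_cost_specificity(params, [314.0], [1.2], rates)


class TestBreakEven:
    def test_zero_incremental_cost_at_break_even(self, params, rates):
        be = ds.break_even_mrm_cost(params, 0.97, rates)
        p = params.replace(cost_mrm=be)
        xm = ds.run_strategy(ds.Modality.XM, p, rates).total_cost
        mrm = ds.run_strategy(ds.Modality.MRM, p, rates).total_cost
        assert mrm - xm == pytest.approx(0.0, abs=0.5)

    def test_strictly_increasing_in_specificity(self, params, rates):
        costs = [
            ds.break_even_mrm_cost(params, s, rates) for s in (0.92, 0.95, 0.99)
        ]
        assert costs[0] < costs[1] < costs[2]

    def test_bad_bracket_raises_with_bounds(self, params, rates):
        with pytest.raises(BracketError, match="bracket"):
            ds.break_even_mrm_cost(params, 0.97, rates, bracket=(1000.0, 2000.0))


class TestDistributions:
    def test_beta_moments_and_domain(self):
        rng = np.random.default_rng(0)
        d = Distribution("beta", cv=0.1)
        x = d.sample(0.4, 20_000, rng)
        assert np.all((x >= 0) & (x <= 1))
        assert x.mean() == pytest.approx(0.4, abs=0.002)
        assert x.std() == pytest.approx(0.04, abs=0.002)

    def test_gamma_moments_and_domain(self):
        rng = np.random.default_rng(0)
        d = Distribution("gamma", cv=0.2)
        x = d.sample(314.0, 20_000, rng)
        assert np.all(x >= 0)
        assert x.mean() == pytest.approx(314.0, rel=0.01)
        assert x.std() == pytest.approx(62.8, rel=0.05)

    def test_boundary_mean_is_degenerate(self):
        rng = np.random.default_rng(0)
        assert np.all(Distribution("beta").sample(1.0, 10, rng) == 1.0)
        assert np.all(Distribution("beta").sample(0.0, 10, rng) == 0.0)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            Distribution("lognormal")


class TestPSA:
    def test_zero_variance_reproduces_base_case(self, params, rates):
        spec = {k: Distribution(d.family, cv=0.0) for k, d in
                default_distributions().items()}
        psa = ds.probabilistic_sa(params, spec, 8, seed=1, rates=rates)
        base = _signed_ratio(params, rates, None)
        icers = psa.incr_cost / psa.incr_effect
        np.testing.assert_allclose(icers, base, rtol=1e-12)
        assert np.ptp(psa.incr_cost) == 0.0

    def test_bit_reproducible_given_seed(self, params, rates):
        a = ds.probabilistic_sa(params, None, 100, seed=7, rates=rates)
        b = ds.probabilistic_sa(params, None, 100, seed=7, rates=rates)
        np.testing.assert_array_equal(a.incr_cost, b.incr_cost)
        np.testing.assert_array_equal(a.incr_effect, b.incr_effect)
        assert a.draws.equals(b.draws)

    def test_chunking_does_not_change_results(self, params, rates):
        a = ds.probabilistic_sa(params, None, 50, seed=3, rates=rates, chunk=7)
        b = ds.probabilistic_sa(params, None, 50, seed=3, rates=rates, chunk=50)
        np.testing.assert_array_equal(a.incr_cost, b.incr_cost)

    def test_unknown_field_rejected(self, params, rates):
        with pytest.raises(ValueError):
            ds.probabilistic_sa(
                params, {"no_such": Distribution("beta")}, 4, 0, rates
            )

    def test_drawn_values_respect_domains(self, params, rates):
        psa = ds.probabilistic_sa(params, None, 200, seed=11, rates=rates)
        probs = psa.draws[[c for c in psa.draws if not c.startswith("cost_")]]
        assert ((probs >= 0) & (probs <= 1)).all().all()
        costs = psa.draws[[c for c in psa.draws if c.startswith("cost_")]]
        assert (costs >= 0).all().all()


class TestCEAC:
    def test_all_dominant_samples_accept_everywhere(self, params, rates):
        psa = ds.probabilistic_sa(params, None, 50, seed=5, rates=rates)
        forced = ds.PSAResult(
            draws=psa.draws,
            cost_ref=np.full(50, 200.0),
            effect_ref=np.full(50, 10.0),
            cost_alt=np.full(50, 100.0),
            effect_alt=np.full(50, 11.0),
            wtp=psa.wtp,
            seed=psa.seed,
        )
        curve = ds.ceac(forced, np.array([0.0, 50_000.0, 150_000.0]))
        np.testing.assert_array_equal(curve.fractions, 1.0)

    def test_single_sample_steps_at_its_icer(self, params, rates):
        one = ds.PSAResult(
            draws=ds.probabilistic_sa(params, None, 1, 0, rates).draws,
            cost_ref=np.array([5810.0]),
            effect_ref=np.array([15.1]),
            cost_alt=np.array([6081.0]),
            effect_alt=np.array([15.12]),
            wtp=100_000.0,
            seed=0,
        )
        curve = ds.ceac(one, np.array([13_500.0, 13_550.0, 13_600.0]))
        # the sample's own ratio is 271 / 0.020 = 13,550
        np.testing.assert_array_equal(curve.fractions, [0.0, 0.0, 1.0])

    def test_endpoint_identities(self, params, rates):
        psa = ds.probabilistic_sa(params, None, 400, seed=9, rates=rates)
        curve = ds.ceac(psa, np.array([0.0, 1e9]))
        assert curve.fractions[0] == np.mean(psa.incr_cost < 0)
        assert curve.fractions[-1] == np.mean(psa.incr_effect > 0)

    def test_invalid_grid_rejected(self, params, rates):
        psa = ds.probabilistic_sa(params, None, 4, seed=2, rates=rates)
        with pytest.raises(ValueError):
            ds.ceac(psa, np.array([2.0, 1.0]))
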