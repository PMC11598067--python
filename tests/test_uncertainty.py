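"""GUM power-product budgets, UPC shares, and the Monte Carlo oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from berrymetrics import (
    Quantity,
    UncertaintySource,
    compatibility_check,
    estimator_rmse_sigma,
    monte_carlo_budget,
    propagate_power_product,
    propagate_sphere_sum,
    sphere_volume,
)


def volume_chain_sources(v=1e6, sv=2.8e5, d=500, sd=25, f=1000, sf=2, r=1.8, sr=0.32):
    return [
        UncertaintySource("v_visible_px", Quantity(v, sv, "px3"), 1),
        UncertaintySource("d", Quantity(d, sd, "mm"), 3),
        UncertaintySource("f", Quantity(f, sf, "px"), -3),
        UncertaintySource("R", Quantity(r, sr, "dimensionless"), 1),
    ]


class TestPowerProduct:
    def test_single_source(self):
        b = propagate_power_product([UncertaintySource("x", Quantity(10, 1, "mm"), 1)])
        assert b.relative_sigma == pytest.approx(0.1)
        assert b.upc == {"x": pytest.approx(100.0)}

    def test_volume_chain_budget(self):
        """Four-source budget of V_b = V_px * (d/f)^3 * R at plausible values."""
        b = propagate_power_product(volume_chain_sources())
        assert b.relative_sigma == pytest.approx(
            math.sqrt(0.28**2 + 9 * 0.05**2 + 9 * 0.002**2 + (0.32 / 1.8) ** 2), rel=1e-9
        )
        assert b.relative_sigma == pytest.approx(0.36409, rel=1e-4)
        assert b.upc["v_visible_px"] == pytest.approx(59.14, abs=0.05)
        assert b.upc["d"] == pytest.approx(16.97, abs=0.05)
        assert b.upc["f"] == pytest.approx(0.03, abs=0.02)
        assert b.upc["R"] == pytest.approx(23.85, abs=0.05)

    def test_upc_sums_to_100(self):
        b = propagate_power_product(volume_chain_sources())
        assert sum(b.upc.values()) == pytest.approx(100.0, abs=1e-9)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 1e4), st.floats(0.0, 0.2), st.sampled_from([-3, -1, 1, 3])
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_upc_sum_and_unit_rescale_invariance(self, spec):
        sources = [
            UncertaintySource(f"s{i}", Quantity(v, v * rel, "dimensionless"), p)
            for i, (v, rel, p) in enumerate(spec)
        ]
        b = propagate_power_product(sources)
        if b.relative_sigma > 0:
            assert sum(b.upc.values()) == pytest.approx(100.0, abs=1e-6)
        # rescaling any source's unit (value and sigma together) leaves UPC unchanged
        rescaled = [
            UncertaintySource(s.name, Quantity(s.quantity.value * 7.3, s.quantity.sigma * 7.3, s.quantity.unit), s.exponent)
            for s in sources
        ]
        b2 = propagate_power_product(rescaled)
        for name in b.upc:
            assert b2.upc[name] == pytest.approx(b.upc[name], abs=1e-9)

    def test_zero_nominal_rejected(self):
        with pytest.raises(ZeroDivisionError):
            propagate_power_product([UncertaintySource("x", Quantity(0, 1, "mm"), 1)])


class TestSphereSum:
    def test_single_berry_sensitivity(self):
        sigma_r = 1 / math.sqrt(3)
        q = propagate_sphere_sum([25.0], sigma_r)
        assert q.sigma == pytest.approx(4 * math.pi * 625 * sigma_r, rel=1e-12)
        assert q.sigma == pytest.approx(4534.50, rel=1e-4)

    def test_matches_finite_difference(self):
        r, h = 17.3, 1e-6
        deriv = (sphere_volume(r + h) - sphere_volume(r - h)) / (2 * h)
        q = propagate_sphere_sum([r], 0.4)
        assert q.sigma == pytest.approx(abs(deriv) * 0.4, rel=1e-6)

    def test_sqrt_n_scaling_for_identical_berries(self):
        one = propagate_sphere_sum([10.0], 0.5).sigma
        many = propagate_sphere_sum([10.0] * 25, 0.5).sigma
        assert many == pytest.approx(5 * one, rel=1e-12)

    def test_fixture_views_average_sigma(self, flame_reference):
        """Mean-radius approximation over the 30 packaged views with the
        1-px type-B annotation uncertainty gives an average sigma close to
        the published 1.8e4 px^3 (per-berry radii were not published)."""
        sig = [
            propagate_sphere_sum([v.r_mean_px] * v.n_visible, 1 / math.sqrt(3)).sigma
            for _, views in flame_reference
            for v in views
        ]
        assert np.mean(sig) == pytest.approx(1.89e4, rel=0.01)
        assert np.mean(sig) == pytest.approx(1.8e4, rel=0.10)


class TestEstimatorRmse:
    def test_zero_for_perfect_estimates(self):
        assert estimator_rmse_sigma([1.0, 2.0], [1.0, 2.0]).sigma == 0

    def test_small_example(self):
        assert estimator_rmse_sigma([-3.0, 4.0], [0.0, 0.0]).sigma == pytest.approx(3.5355339, rel=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimator_rmse_sigma([1.0], [1.0, 2.0])


class TestMonteCarloOracle:
    def test_zero_sigma_sources_give_zero_spread(self):
        srcs = volume_chain_sources(sv=0, sd=0, sf=0, sr=0)
        mc = monte_carlo_budget(srcs, n_samples=20_000, seed=1)
        assert mc.combined_sigma == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_linear_budget_at_paper_scale(self):
        """The four-source chain: MC vs linear within a few % (sigma_R/R is
        large, so exact agreement is not expected)."""
        srcs = volume_chain_sources()
        lin = propagate_power_product(srcs)
        mc = monte_carlo_budget(srcs, n_samples=400_000, seed=7)
        assert mc.relative_sigma == pytest.approx(lin.relative_sigma, rel=0.05)
        for name in lin.upc:
            assert mc.upc[name] == pytest.approx(lin.upc[name], abs=1.0)

    def test_small_sigma_regime_within_2pct(self, rng):
        """Linear GUM matches MC within 2% in the small-uncertainty regime,
        i.e. when each source's effective relative contribution |p| sigma/x
        stays below 5% (for cubed sources the bare sigma/x must be smaller
        still -- the linearization error scales with the contribution)."""
        for _ in range(5):
            srcs = []
            for i in range(4):
                p = int(rng.choice([-3, -1, 1, 3]))
                value = float(rng.uniform(0.5, 100))
                rel = float(rng.uniform(0.005, 0.05)) / abs(p)
                srcs.append(
                    UncertaintySource(f"s{i}", Quantity(value, value * rel, "dimensionless"), p)
                )
            lin = propagate_power_product(srcs)
            mc = monte_carlo_budget(srcs, n_samples=200_000, seed=int(rng.integers(2**31)))
            assert mc.relative_sigma == pytest.approx(lin.relative_sigma, rel=0.02)


class TestCompatibility:
    def test_zero_error_compatible(self):
        assert compatibility_check(0.0, 1.0)

    def test_three_sigma_incompatible_at_k2(self):
        assert not compatibility_check(3.0, 1.0, k=2)

    def test_boundary_inclusive(self):
        assert compatibility_check(2.0, 1.0, k=2)

    def test_zero_sigma_only_for_zero_error(self):
        assert compatibility_check(0.0, 0.0)
        assert not compatibility_check(0.1, 0.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            compatibility_check(1.0, -1.0)
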