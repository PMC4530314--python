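"""Boundary function, artificial transfer, and the composed biophysical transfer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dendtf import (
    ArtificialParams,
    BoundaryParams,
    DendriteGeometry,
    InputPattern,
    artificial_transfer,
    boundary_G,
    check_boundary_saturation,
    fit_artificial,
    saturation_amplitude,
    soma_decay_weights,
    sum_branches,
    transfer_bio,
    transfer_bio_detailed,
    transfer_single,
)


class TestBoundaryG:
    def test_symmetric_parameters_pass_through_zero(self, boundary12):
        assert boundary_G(0.0, boundary12) == 0.0

    def test_asymptotes_to_bounds(self, boundary12):
        assert boundary_G(1e6, boundary12) == pytest.approx(12.0)
        assert boundary_G(-1e6, boundary12) == pytest.approx(-12.0)

    def test_near_identity_inside_band(self, boundary12):
        assert abs(boundary_G(1.0, boundary12) - 1.0) < 0.05

    def test_monotone_nondecreasing(self, boundary12):
        v = np.linspace(-60, 60, 4000)
        assert np.all(np.diff(boundary_G(v, boundary12)) >= 0)

    @pytest.mark.parametrize("v", [-30.0, -5.0, 0.0, 1.0, 7.0, 11.0, 30.0])
    def test_closed_form_matches_quadrature_of_integrand(self, boundary12, v):
        bp = boundary12

        def integrand(u):
            lower = 1.0 / (1.0 + math.exp(-bp.alpha_l * (u - bp.b_l)))
            upper = 1.0 / (1.0 + math.exp(-bp.alpha_u * (u - bp.b_u)))
            return lower - upper

        numeric = bp.b_l + quad(integrand, -400.0, v, limit=500)[0]
        assert boundary_G(v, bp) == pytest.approx(numeric, abs=1e-6)

    def test_asymmetric_bounds_validated(self):
        with pytest.raises(ValueError):
            BoundaryParams(5.0, -5.0, 0.5, 0.5)


class TestArtificialTransfer:
    def test_zero_input_below_threshold_is_near_zero(self, boundary12):
        ap = ArtificialParams(c_d=8.0, a_d=1.0, b_d=50.0)
        assert abs(artificial_transfer([0.0, 0.0, 0.0], ap, boundary12)) < 1e-12

    def test_large_input_saturates_to_upper_bound(self, boundary12):
        ap = ArtificialParams(c_d=8.0, a_d=1.0, b_d=5.0)
        assert artificial_transfer([500.0, 500.0], ap, boundary12) == pytest.approx(12.0)

    def test_sigmoid_midpoint_substitution(self, boundary12):
        ap = ArtificialParams(c_d=6.0, a_d=2.0, b_d=4.0)
        out = artificial_transfer([1.0, 3.0], ap, boundary12)  # sum == b_d
        assert out == pytest.approx(boundary_G(ap.c_d / 2 + ap.b_d, boundary12))

    def test_permutation_invariance(self, boundary12):
        ap = ArtificialParams(c_d=6.0, a_d=0.7, b_d=4.0)
        a = artificial_transfer([0.5, 2.0, 3.5], ap, boundary12)
        b = artificial_transfer([3.5, 0.5, 2.0], ap, boundary12)
        assert a == b


class TestTransferBio:
    def test_no_input_gives_no_output(self, two_site_geometry, membrane, boundary12,
                                      opening_filtered):
        out = transfer_bio(InputPattern((0.0, 0.0)), two_site_geometry, membrane,
                           boundary12, open_dist=opening_filtered)
        assert abs(out) < 0.01

    def test_weak_single_input_is_linear(self, membrane, boundary12, opening_filtered):
        geom = DendriteGeometry((200.0,), 77.0)
        out = transfer_bio(InputPattern((1.0,)), geom, membrane, boundary12,
                           open_dist=opening_filtered)
        delta = math.exp(-200.0 / 77.0)
        assert out == pytest.approx(delta, rel=0.05)

    def test_infinite_separation_sums_linearly(self, membrane, boundary12,
                                               opening_filtered):
        geom = DendriteGeometry((200.0, 10200.0), 77.0)
        both = transfer_bio(InputPattern((20.0, 20.0)), geom, membrane, boundary12,
                            open_dist=opening_filtered)
        singles = sum_branches(
            transfer_bio(InputPattern((20.0, 0.0)), geom, membrane, boundary12,
                         open_dist=opening_filtered),
            transfer_bio(InputPattern((0.0, 20.0)), geom, membrane, boundary12,
                         open_dist=opening_filtered),
        )
        assert abs(both - singles) < 1e-6

    def test_output_respects_boundary_bounds(self, two_site_geometry, membrane,
                                             boundary12, opening_filtered):
        for v in (0.0, 30.0, 70.0, 500.0):
            out = transfer_bio(InputPattern((v, v)), two_site_geometry, membrane,
                               boundary12, open_dist=opening_filtered)
            assert boundary12.b_l < out < boundary12.b_u

    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0), st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_monotone_in_each_input(self, membrane, boundary12, opening_filtered,
                                    v1, v2, bump):
        geom = DendriteGeometry((200.0, 260.0), 77.0)

        def T(a, b):
            return transfer_bio(InputPattern((a, b)), geom, membrane, boundary12,
                                open_dist=opening_filtered)

        base = T(v1, v2)
        assert T(v1 + bump, v2) >= base - 1e-9
        assert T(v1, v2 + bump) >= base - 1e-9

    def test_distribution_model_requires_burst_dist(self, two_site_geometry, membrane,
                                                    boundary12, opening_filtered):
        with pytest.raises(ValueError):
            transfer_bio(InputPattern((5.0, 5.0)), two_site_geometry, membrane,
                         boundary12, model="distribution", open_dist=opening_filtered)

    def test_mismatched_pattern_length_raises(self, two_site_geometry, membrane,
                                              boundary12, opening_filtered):
        with pytest.raises(ValueError):
            transfer_bio(InputPattern((1.0,)), two_site_geometry, membrane,
                         boundary12, open_dist=opening_filtered)

    def test_detailed_output_stages_are_consistent(self, two_site_geometry, membrane,
                                                   boundary12, opening_filtered):
        detail = transfer_bio_detailed(InputPattern((30.0, 30.0)), two_site_geometry,
                                       membrane, boundary12, open_dist=opening_filtered)
        delta = soma_decay_weights(two_site_geometry)
        total = np.dot(delta, np.add(detail["inputs_mv"], detail["per_site_nmda_mv"]))
        assert detail["soma_mv"] == pytest.approx(boundary_G(total, boundary12))


class TestTransferSingle:
    def test_rest_input_stays_near_rest(self, membrane):
        assert transfer_single(0.0, membrane) < 0.01

    def test_far_above_threshold_hits_saturation_exactly(self, membrane):
        # v0 + (sat - v0) * 1 == sat regardless of the excess
        sat = saturation_amplitude(membrane)
        assert transfer_single(65.0, membrane, delta=0.5) == pytest.approx(0.5 * sat,
                                                                           rel=1e-6)

    def test_monotone_on_dense_grid(self, membrane):
        grid = np.linspace(0.0, 70.0, 1000)
        vals = [transfer_single(v, membrane) for v in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_delta_rejected(self, membrane):
        with pytest.raises(ValueError):
            transfer_single(5.0, membrane, delta=0.0)


class TestEquivalences:
    def test_single_site_bio_matches_bounded_single_transfer(self, membrane, boundary12,
                                                             opening_filtered):
        # well inside the boundary's linear band both forms reduce to delta*v
        geom = DendriteGeometry((200.0,), 77.0)
        delta = float(soma_decay_weights(geom)[0])
        for v in (0.5, 1.0, 5.0, 10.0):
            bio = transfer_bio(InputPattern((v,)), geom, membrane, boundary12,
                               open_dist=opening_filtered)
            single = boundary_G(transfer_single(v, membrane, delta), boundary12)
            assert abs(bio - single) < 0.1

    def test_artificial_form_reproduces_single_location_bio(self, membrane, boundary12,
                                                            opening_filtered):
        geom = DendriteGeometry((200.0,), 77.0)
        grid = np.linspace(0.0, 10.0, 41)
        ap = fit_artificial(geom, membrane, boundary12, opening_filtered, grid)
        delta = float(soma_decay_weights(geom)[0])
        err = max(
            abs(artificial_transfer([delta * v], ap, boundary12)
                - transfer_bio(InputPattern((v,)), geom, membrane, boundary12,
                               open_dist=opening_filtered))
            for v in grid
        )
        assert err < 0.5


def test_boundary_saturation_check_warns_when_bound_too_wide(membrane, opening_filtered):
    geom = DendriteGeometry((200.0,), 77.0)
    ok_bp = BoundaryParams.symmetric(5.0, 0.5)   # one spike ~5.2 mV at soma
    assert check_boundary_saturation(geom, membrane, ok_bp)
    wide_bp = BoundaryParams.symmetric(40.0, 0.5)
    with pytest.warns(UserWarning):
        assert not check_boundary_saturation(geom, membrane, wide_bp)
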