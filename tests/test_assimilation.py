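"""PIV datasets, the weighted plane misfit, and sigma -> weight calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wlsfem import (FlowState, PIVDataSet, PIVTerm, build_box_mesh, data_at_time,
                    flag_outliers, make_plane_frame, plane_misfit, read_piv_csv,
                    weight_from_sigma, write_piv_csv)
from wlsfem.assimilation import FrameMissingError
from wlsfem.geometry import PlaneFrame


def line_frame():
    # vertical line x = 0.5 in a unit square, origin at mid-height
    return make_plane_frame([0.5, 0.5], [1.0, 0.0])


def make_line_dataset(values_fn, times=(0.0, 1.0), n=5, sigma=0.1, half=0.4):
    frame = line_frame()
    s1 = np.linspace(-half, half, n)
    dirs = frame.in_plane_directions()
    vel = np.zeros((len(times), n, 1, 2))
    pts = frame.to_world(np.stack([s1, np.zeros(n)], axis=-1))
    for it, t in enumerate(times):
        vel[it, :, 0, :] = values_fn(pts, t) @ dirs.T
    return PIVDataSet(frame, s1, np.array([0.0]), vel, sigma,
                      np.asarray(times, dtype=float), dirs)


class TestWeightFromSigma:
    def test_inverse_variance(self):
        assert weight_from_sigma(1.0) == pytest.approx(1.0)
        assert weight_from_sigma(0.5) == pytest.approx(4.0)

    def test_normalized_to_most_accurate_stream(self):
        assert weight_from_sigma(0.1, normalize_to=0.1) == pytest.approx(1.0)
        assert weight_from_sigma(0.2, normalize_to=0.1) == pytest.approx(0.25)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(ValueError):
            weight_from_sigma(bad)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3))
    def test_weight_scaling_property(self, sa, sb):
        # w(sa)/w(sb) = (sb/sa)^2, and normalization preserves the ratio
        ra = weight_from_sigma(sa) / weight_from_sigma(sb)
        rb = weight_from_sigma(sa, normalize_to=sb)
        assert ra == pytest.approx((sb / sa) ** 2, rel=1e-12)
        assert rb == pytest.approx(ra, rel=1e-12)


class TestDataAtTime:
    def test_exact_frame_returned_identically(self):
        ds = make_line_dataset(lambda x, t: x * (1 + t))
        fd = data_at_time(ds, 1.0)
        np.testing.assert_array_equal(fd.values, ds.velocities[1])

    def test_linear_interpolation_midway(self):
        ds = make_line_dataset(lambda x, t: x * (1 + t))
        fd = data_at_time(ds, 0.5, mode="linear")
        np.testing.assert_allclose(
            fd.values, 0.5 * (ds.velocities[0] + ds.velocities[1]), atol=1e-14)

    def test_none_mode_skips_unmatched_times(self):
        ds = make_line_dataset(lambda x, t: x)
        with pytest.raises(FrameMissingError):
            data_at_time(ds, 0.3, mode="none")

    def test_no_extrapolation_outside_span(self):
        ds = make_line_dataset(lambda x, t: x)
        with pytest.raises(ValueError, match="span"):
            data_at_time(ds, 2.0)

    def test_inplane_interpolation_exact_for_affine_data(self):
        # bilinear interpolation reproduces in-plane-affine vector data exactly
        frame = PlaneFrame(np.zeros(3), np.array([1.0, 0, 0]),
                           np.array([0.0, 1.0, 0]), np.array([0.0, 0, 1.0]))
        s1 = np.linspace(0, 1, 4)
        s2 = np.linspace(0, 1, 3)
        S1, S2 = np.meshgrid(s1, s2, indexing="ij")
        vals = np.stack([2 * S1 - S2 + 0.5, S1 + 3 * S2], axis=-1)[None]
        ds = PIVDataSet(frame, s1, s2, vals, 0.01, [0.0],
                        frame.in_plane_directions())
        fd = data_at_time(ds, 0.0)
        q = np.array([[0.37, 0.61], [0.8, 0.15]])
        expect = np.stack([2 * q[:, 0] - q[:, 1] + 0.5,
                           q[:, 0] + 3 * q[:, 1]], axis=-1)
        np.testing.assert_allclose(fd(q), expect, atol=1e-12)


class TestPlaneMisfit:
    @pytest.fixture()
    def mesh(self):
        return build_box_mesh([1.0, 1.0], [4, 4])

    def test_zero_when_trace_matches_data(self, mesh):
        ds = make_line_dataset(lambda x, t: np.stack(
            [x[:, 1] * 0 + 0.3, x[:, 0] * 0], axis=-1))
        st = FlowState.zero(mesh)
        st.v[:, 0] = 0.3
        val, R = plane_misfit(st, PIVTerm(ds, 1.0), mesh, 0.0)
        assert val < 1e-26
        np.testing.assert_allclose(R, 0.0, atol=1e-13)

    def test_zero_weight_contributes_nothing(self, mesh):
        ds = make_line_dataset(lambda x, t: np.ones_like(x))
        st = FlowState.zero(mesh)
        val, _ = plane_misfit(st, PIVTerm(ds, 0.0), mesh, 0.0)
        assert val == 0.0

    def test_constant_offset_closed_form(self, mesh):
        # |v - g| = c along a line of length L with uniform h:
        # misfit = (w/h) c^2 L
        c, w = 0.25, 2.0
        ds = make_line_dataset(lambda x, t: np.zeros_like(x), n=9, half=0.375)
        st = FlowState.zero(mesh)
        st.v[:, 0] = c
        val, _ = plane_misfit(st, PIVTerm(ds, w), mesh, 0.0)
        h = 0.25
        L = 0.75
        assert val == pytest.approx(w / h * c ** 2 * L, rel=1e-12)

    def test_masked_vectors_contribute_nothing(self, mesh):
        ds = make_line_dataset(lambda x, t: np.zeros_like(x), n=9, half=0.375)
        st = FlowState.zero(mesh)
        st.v[:, 0] = 1.0
        full, _ = plane_misfit(st, PIVTerm(ds, 1.0), mesh, 0.0)
        ds.validity_mask[:, :4] = False
        part, R = plane_misfit(st, PIVTerm(ds, 1.0), mesh, 0.0)
        assert part < full
        assert R.shape[0] == 5


def test_unmatched_frame_skips_the_piv_term_for_the_step():
    """With time_mode='none' and no stored frame at the step time, the PIV
    term drops out of the step (byte-identical to the data-free solve)."""
    from wlsfem import solve_timestep
    from wlsfem.scenarios import vortex_line_dataset, vortex_step_problem
    flow, mesh, prob0, prev = vortex_step_problem(4)
    sol0 = solve_timestep(prob0, initial_guess=prev, tol=1e-9)
    ds = vortex_line_dataset(flow, 0.11, sigma=0.05, seed=1)  # frames miss t=0.1
    _, _, prob1, _ = vortex_step_problem(4)
    prob1.piv_terms = [PIVTerm(ds, 1.0, time_mode="none")]
    sol1 = solve_timestep(prob1, initial_guess=prev, tol=1e-9)
    assert sol0.pack().tobytes() == sol1.pack().tobytes()


def test_data_influence_decays_away_from_the_plane():
    """The difference between assimilating (w=1) and not (w=0) is largest on
    the PIV plane and decays (non-strictly) on parallel planes further away."""
    from wlsfem import evaluate_field, solve_timestep
    from wlsfem.scenarios import vortex_line_dataset, vortex_step_problem
    flow, mesh, prob0, prev = vortex_step_problem(8)
    ds = vortex_line_dataset(flow, 0.1, sigma=0.2, seed=3, n_pts=13)
    sol0 = solve_timestep(prob0, initial_guess=prev, tol=1e-10)
    _, _, prob1, _ = vortex_step_problem(8, piv_terms=[PIVTerm(ds, 1.0)])
    sol1 = solve_timestep(prob1, initial_guess=prev, tol=1e-10)
    dv = sol1.v - sol0.v
    ys = np.linspace(0.05, 0.95, 15)
    means = []
    for dist in (0.0, 0.125, 0.25, 0.375):
        means.append(np.mean([np.linalg.norm(
            evaluate_field(mesh, dv, [0.5 + dist, y])[0]) for y in ys]))
    assert np.all(np.diff(means) <= 1e-12)


class TestOutlierFlagging:
    def test_gross_vector_flagged_and_neighbours_kept(self):
        frame = line_frame()
        n = 9
        s1 = np.linspace(-0.4, 0.4, n)
        vel = np.zeros((1, n, 1, 2))
        vel[0, :, 0, 0] = 1.0
        vel[0, 4, 0, :] = [8.0, -7.0]  # the circled-vector analogue
        ds = PIVDataSet(frame, s1, np.array([0.0]), vel, 0.1, [0.0],
                        frame.in_plane_directions())
        flags = flag_outliers(ds, k=5.0)
        assert flags[0, 4, 0]
        assert flags.sum() == 1


class TestCSVRoundTrip:
    def test_bit_stable(self, tmp_path, rng):
        frame = line_frame()
        n = 6
        s1 = np.linspace(-0.3, 0.3, n)
        vel = rng.normal(size=(3, n, 1, 2))
        mask = rng.random((3, n, 1)) > 0.2
        ds = PIVDataSet(frame, s1, np.array([0.0]), vel, 0.07,
                        [0.0, 0.1, 0.2], frame.in_plane_directions(), mask)
        path = tmp_path / "piv.csv"
        write_piv_csv(ds, str(path))
        back = read_piv_csv(str(path))
        np.testing.assert_array_equal(back.velocities, ds.velocities)
        np.testing.assert_array_equal(back.validity_mask, ds.validity_mask)
        np.testing.assert_array_equal(back.times, ds.times)
        np.testing.assert_array_equal(back.s1, ds.s1)
        assert back.sigma == ds.sigma
        np.testing.assert_array_equal(back.frame.origin, ds.frame.origin)
        np.testing.assert_array_equal(back.directions, ds.directions)
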