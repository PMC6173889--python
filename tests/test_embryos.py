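"""Embryo layout, drag law and trajectory integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from etflow.embryos import (
    MORSI_ALEXANDER,
    EmbryoParams,
    EmbryoState,
    drag_coefficient,
    drag_response,
    initial_positions,
    relative_reynolds,
    step_embryo,
)

EMBRYO = EmbryoParams()  # r_e = 0.05 mm, rho_e = 1000 kg/m^3


class TestInitialLayout:
    def test_equal_area_circles(self):
        """The ten zones bounded by r_i = sqrt(i/10)(r_c - r_e) have equal
        areas pi (r_c - r_e)^2 / 10."""
        r_c, r_e = 0.3, 0.05
        i = np.arange(0, 11)
        r = np.sqrt(i / 10.0) * (r_c - r_e)
        assert np.allclose(np.diff(np.pi * r**2),
                           np.pi * (r_c - r_e) ** 2 / 10.0)
        assert r[10] == pytest.approx(0.25)

    def test_midpoint_offsets(self):
        y = initial_positions(0.3, 0.05)
        assert y.shape == (10,)
        assert y[0] == pytest.approx(np.sqrt(0.1) * 0.25 / 2)   # ~0.0395 mm
        assert y[-1] == pytest.approx((np.sqrt(0.9) + 1.0) * 0.25 / 2)
        assert (np.diff(y) > 0).all()
        assert y[-1] < 0.3   # all inside the bore

    def test_embryo_radius_must_fit_bore(self):
        with pytest.raises(ValueError):
            initial_positions(0.3, 0.3)


class TestRelativeReynolds:
    def test_no_slip_is_zero(self):
        assert relative_reynolds(1000.0, 0.001, 5e-5,
                                 (0.1, 0.0), (0.1, 0.0)) == 0.0

    def test_reference_case_discharge(self):
        re = relative_reynolds(1000.0, 0.001, 5e-5, (0.0707, 0.0), (0.0, 0.0))
        assert re == pytest.approx(7.07)

    def test_linear_in_radius(self):
        args = (1000.0, 0.001, (0.01, 0.0), (0.0, 0.0))
        one = relative_reynolds(args[0], args[1], 5e-5, args[2], args[3])
        two = relative_reynolds(args[0], args[1], 1e-4, args[2], args[3])
        assert two == pytest.approx(2 * one)


class TestDragLaw:
    @pytest.mark.parametrize("re,cd", [(0.05, 480.0), (0.01, 2400.0)])
    def test_stokes_band_is_24_over_re(self, re, cd):
        assert drag_coefficient(re) == pytest.approx(cd)

    def test_piecewise_bands_nearly_continuous(self):
        """The published coefficients agree within 5% at every breakpoint."""
        for (hi, *_), nxt in zip(MORSI_ALEXANDER[:-1], MORSI_ALEXANDER[1:]):
            a1, a2, a3 = nxt[1:]
            below = drag_coefficient(hi)
            above = a1 + a2 / hi + a3 / hi**2
            assert abs(above - below) / below < 0.05

    def test_negative_reynolds_rejected(self):
        with pytest.raises(ValueError):
            drag_coefficient(-1.0)

    def test_stokes_relaxation_rate(self):
        """Stokes limit of the standard form: beta = 9 mu / (2 rho_e r_e^2)."""
        beta = drag_response(0.799, 1259.9, np.inf, 0.0, EMBRYO, "standard")
        assert beta == pytest.approx(9 * 0.799 / (2 * 1000 * (5e-5) ** 2))
        assert beta == pytest.approx(1.4382e6, rel=1e-4)

    def test_printed_form_is_exactly_twice_standard(self):
        for re in (0.0, 0.5, 5.0):
            cd = np.inf if re == 0 else drag_coefficient(re)
            std = drag_response(0.01, 1000.0, cd, re, EMBRYO, "standard")
            pap = drag_response(0.01, 1000.0, cd, re, EMBRYO, "paper")
            assert pap == pytest.approx(2 * std)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            drag_response(0.01, 1000.0, 24.0, 1.0, EMBRYO, "other")


class TestStepEmbryo:
    def test_no_slip_moves_in_a_straight_line(self):
        s = EmbryoState(id=1, x=0.0, y=0.0, vx=0.01, vy=0.005)
        out = step_embryo(s, (0.01, 0.005), 1000.0, 0.001, 0.1, EMBRYO)
        assert out.x == pytest.approx(0.001)
        assert out.y == pytest.approx(0.0005)
        assert out.vx == pytest.approx(0.01)

    def test_stokes_decay_matches_closed_form(self):
        """In quiescent fluid a small initial velocity decays as
        v0 exp(-beta t) and the total displacement tends to v0/beta."""
        mu, rho = 1e-6, 1000.0    # thin fluid so beta dt stays moderate
        beta = 9 * mu / (2 * EMBRYO.density * EMBRYO.radius**2)
        v0 = 1e-6                 # Re_r stays deep in the Stokes band
        dt = 0.02 / beta
        s = EmbryoState(id=1, x=0.0, y=0.0, vx=v0, vy=0.0)
        for k in range(200):
            s = step_embryo(s, (0.0, 0.0), rho, mu, dt, EMBRYO)
        t = 200 * dt
        assert s.vx == pytest.approx(v0 * np.exp(-beta * t), rel=1e-3)
        # run long enough to exhaust the momentum
        for k in range(2000):
            s = step_embryo(s, (0.0, 0.0), rho, mu, dt, EMBRYO)
        assert s.x == pytest.approx(v0 / beta, rel=1e-2)

    def test_tracer_limit_velocity_lock(self):
        """For beta dt >> 1 the embryo velocity equals the local fluid
        velocity to better than 0.1% after a single step."""
        mu = 0.799
        beta = 9 * mu / (2 * EMBRYO.density * EMBRYO.radius**2)
        dt = 1e-4
        assert beta * dt > 10
        s = EmbryoState(id=1, x=0.0, y=0.0, vx=0.0, vy=0.0)
        out = step_embryo(s, (0.05, 0.01), 1259.9, mu, dt, EMBRYO)
        assert abs(out.vx - 0.05) / 0.05 < 1e-3
        assert abs(out.vy - 0.01) / 0.01 < 1e-3

    def test_tracer_matches_high_order_streakline(self):
        """A neutrally buoyant, vanishing-size embryo follows the passive
        tracer path of a steady analytic vortex within integration
        tolerance (independent Runge–Kutta oracle)."""
        omega = 5.0

        def velocity(x, y):
            return -omega * y, omega * x

        params = EmbryoParams(radius=1e-5)
        dt = 1e-4
        s = EmbryoState(id=1, x=0.01, y=0.0)
        for _ in range(1000):                     # 0.1 s, half a turn
            u = velocity(s.x, s.y)
            s = step_embryo(s, u, 1000.0, 0.8, dt, params)
        oracle = solve_ivp(lambda t, z: velocity(*z), (0.0, 0.1),
                           [0.01, 0.0], rtol=1e-10, atol=1e-14)
        xe, ye = oracle.y[0, -1], oracle.y[1, -1]
        err = np.hypot(s.x - xe, s.y - ye) / 0.01
        assert err < 5e-3

    def test_frozen_embryo_does_not_move(self):
        s = EmbryoState(id=1, x=-0.001, y=0.0, vx=0.1, status="exited_cervix")
        out = step_embryo(s, (1.0, 0.0), 1000.0, 0.001, 0.1, EMBRYO)
        assert out is s


class TestDragFormInsensitivity:
    def test_delivery_sites_insensitive_to_drag_form(self):
        """With beta dt >> 1 throughout, toggling between the printed drag
        prefactor and the conventional one moves the delivery sites by far
        less than one cell."""
        from etflow.cases import builtin_case, run_case

        finals = {}
        for form in ("standard", "paper"):
            c = builtin_case(1, withdrawal=False)
            c.t_inj = 0.4
            c.injected_volume_uL = 8.0   # reference-case inlet speed
            c.drag_form = form
            r = run_case(c)
            finals[form] = np.array(
                [(tr.states[-1].x, tr.states[-1].y) for tr in r.trajectories])
        d = np.abs(finals["standard"] - finals["paper"]).max()
        assert d < 0.5e-3   # < one coarse cell (0.5-1 mm)


class TestTrackAll:
    def test_in_catheter_trajectories_parallel_to_axis(self):
        """Before discharge the embryos ride the bore flow: ten independent
        trajectories, straight lines parallel to the axial direction."""
        from dataclasses import replace

        from etflow.cases import _FaceProvider, builtin_case
        from etflow.embryos import track_all
        from etflow.geometry import build_geometry, build_mesh

        c = builtin_case(1, withdrawal=False)
        outline = build_geometry(c.geometry)
        mesh = build_mesh(outline, h=c.h)
        from etflow.flow import FlowSolver
        sol = FlowSolver(mesh, c.phase1, c.phase2, replace(c.solver),
                         _FaceProvider(mesh, c))
        sol.alpha[mesh.bore_mask(0.0)] = 1.0
        trajectories = track_all(sol, outline, 0.05)
        assert len(trajectories) == 10
        y0 = [tr.states[0].y for tr in trajectories]
        for tr, y in zip(trajectories, y0):
            times = np.asarray(tr.times)
            assert (np.diff(times) > 0).all()
            assert tr.states[-1].status == "in_catheter"
            assert tr.states[-1].x > tr.states[0].x      # advancing
            assert abs(tr.states[-1].y - y) < 1e-6       # parallel to x
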