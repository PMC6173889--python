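"""Mixture-flow solver behaviour: analytic benchmarks and invariants."""

import numpy as np
import pytest

from etflow.cases import builtin_case, run_case
from etflow.flow import (
    FlowSolver,
    FluidPhase,
    SolverSettings,
    inlet_velocity,
    mixture_properties,
)
from etflow.geometry import box_mesh

WATER = FluidPhase(rho=1000.0, mu=0.001)
UTERINE = FluidPhase(rho=1259.9, mu=0.799)


class TestMixtureProperties:
    @pytest.mark.parametrize("alpha,expect", [
        (1.0, (1000.0, 0.001)),
        (0.0, (1259.9, 0.799)),
        (0.5, (1129.95, 0.400)),
    ])
    def test_linear_blend(self, alpha, expect):
        rho, mu = mixture_properties(alpha, WATER, UTERINE)
        assert rho == pytest.approx(expect[0])
        assert mu == pytest.approx(expect[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_properties(1.2, WATER, UTERINE)


class TestInletVelocity:
    def test_tabulated_speeds(self):
        assert inlet_velocity(20.0, 1.0, 0.3) == pytest.approx(70.7, abs=0.05)
        assert inlet_velocity(20.0, 15.0, 0.3) == pytest.approx(4.72, abs=0.005)
        assert inlet_velocity(0.0, 1.0, 0.3) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            inlet_velocity(20.0, 0.0, 0.3)


def _still_box():
    mesh, fs = box_mesh(0.01, 0.004, 10, 6, {
        "W": ("wall", 0.0, 0.0), "E": ("pressure", 0.0),
        "S": ("symmetry",), "N": ("wall", 0.0, 0.0)})
    return mesh, fs


class TestEquilibriumAndBenchmarks:
    def test_quiescent_field_stays_at_rest(self):
        mesh, fs = _still_box()
        sol = FlowSolver(mesh, WATER, WATER,
                         SolverSettings(dt=0.01), lambda t: fs)
        sol.alpha[:] = 0.5
        for _ in range(3):
            sol.step()
        assert np.abs(sol.u).max() < 1e-12
        assert np.abs(sol.v).max() < 1e-12
        assert np.allclose(sol.alpha, 0.5)

    @staticmethod
    def _poiseuille_error(ncells: int, local_gradient: bool = False) -> float:
        """Max relative error of the half-channel profile against the
        analytic plane-Poiseuille solution.  With ``local_gradient`` the
        analytic profile is built from the computed axial pressure slope,
        isolating the discretisation error from the small entrance loss."""
        L, H, mu, dp = 0.01, 0.001, 0.01, 1.0
        mesh, fs = box_mesh(L, H, 30, ncells, {
            "W": ("pressure", dp), "E": ("pressure", 0.0),
            "S": ("symmetry",), "N": ("wall", 0.0, 0.0)})
        ph = FluidPhase(1000.0, mu)
        sol = FlowSolver(mesh, ph, ph,
                         SolverSettings(dt=0.05, tol=1e-6, max_inner=400),
                         lambda t: fs)
        for _ in range(40):
            sol.step()
        u = sol.u[:, 15]
        if local_gradient:
            px = sol.p.mean(axis=0)
            grad = (px[7] - px[22]) / (mesh.xc[22] - mesh.xc[7])
        else:
            grad = dp / L
        ua = grad / (2 * mu) * (H**2 - mesh.yc**2)
        return float(np.abs(u - ua).max() / ua.max())

    def test_plane_poiseuille_within_3_percent(self):
        assert self._poiseuille_error(20) < 0.03

    def test_poiseuille_error_decreases_on_refinement(self):
        fine = self._poiseuille_error(20, local_gradient=True)
        coarse = self._poiseuille_error(7, local_gradient=True)
        assert fine < coarse


class TestVolumeFractionTransport:
    def test_step_profile_advects_monotonically_and_conserves(self):
        """A step of medium advected through a channel stays in [0, 1],
        remains monotone along the flow and conserves its volume budget."""
        U = 0.01
        mesh, fs = box_mesh(0.02, 0.002, 40, 4, {
            "W": ("flux", U, 0.0, 0.0), "E": ("pressure", 0.0),
            "S": ("symmetry",), "N": ("symmetry",)})
        sol = FlowSolver(mesh, WATER, WATER,
                         SolverSettings(dt=2e-3, max_inner=300),
                         lambda t: fs)
        sol.alpha[:, :10] = 1.0     # band of medium in the first quarter
        v0 = sol.alpha_volume()
        x0 = 0.0025                 # initial band centroid
        for _ in range(100):        # band travels ~ half the channel
            sol.step()
        a = sol.alpha
        assert a.min() >= 0.0 and a.max() <= 1.0 + 1e-12
        # no new extrema: the advected band stays unimodal along x
        prof = a.mean(axis=0)
        sign_changes = np.abs(np.diff(np.sign(
            np.diff(prof)[np.abs(np.diff(prof)) > 1e-9]))).sum() / 2
        assert sign_changes <= 1
        # the band centroid translates at exactly the carrier speed
        centroid = float((prof * mesh.xc * mesh.dx).sum()
                         / (prof * mesh.dx).sum())
        assert centroid == pytest.approx(x0 + U * sol.t, rel=0.02)
        budget = v0 + sol.budget.influx - sol.budget.outflux
        assert sol.alpha_volume() == pytest.approx(budget, rel=1e-10)

    def test_injection_budget_closes_within_one_percent(self):
        """Domain-integrated medium volume plus cumulative outflow equals
        the injected volume during a short reference-case injection."""
        c = builtin_case(1, withdrawal=False)
        c.t_inj = 0.25
        c.injected_volume_uL = 5.0    # same 70.7 mm/s inlet speed
        r = run_case(c)
        assert r.mass_budget_error < 0.01
        for snap in r.snapshots:
            assert snap.alpha.min() >= 0.0
            assert snap.alpha.max() <= 1.0 + 1e-12


def _jet_box(half: bool):
    """Box with a centred inlet slot on the west wall; ``half=True`` models
    the upper half with a symmetry plane at y = 0."""
    U = 0.02
    ly, ny = (0.004, 16) if half else (0.008, 32)

    def west(y):
        yy = y if half else abs(y - 0.004)
        return ("flux", U, 0.0, 1.0) if yy < 0.001 else ("wall", 0.0, 0.0)

    tags = {"W": west, "E": ("pressure", 0.0), "N": ("wall", 0.0, 0.0),
            "S": ("symmetry",) if half else ("wall", 0.0, 0.0)}
    mesh, fs = box_mesh(0.02, ly, 40, ny, tags)
    sol = FlowSolver(mesh, FluidPhase(1000.0, 0.005), FluidPhase(1030.0, 0.05),
                     SolverSettings(dt=2e-3, max_inner=300), lambda t: fs)
    for _ in range(50):
        sol.step()
    return sol


class TestSymmetryAndLimits:
    def test_half_domain_matches_mirrored_full_domain(self):
        """The half-domain solution with a symmetry plane equals the upper
        half of the full-domain solution of the mirrored problem."""
        half = _jet_box(half=True)
        full = _jet_box(half=False)
        # the full solution must itself be mirror symmetric to round-off
        assert np.abs(full.u - full.u[::-1, :]).max() < 1e-12
        # half-domain agrees within discretisation error (the symmetry BC
        # and the mirrored interior stencil differ at O(h) near the plane)
        scale = np.abs(half.u).max()
        assert np.abs(full.u[16:, :] - half.u).max() / scale < 0.01
        assert np.abs(full.v[16:, :] - half.v).max() / scale < 0.01
        assert np.abs(full.alpha[16:, :] - half.alpha).max() < 0.01

    def test_equal_properties_makes_alpha_passive(self):
        """With identical phase properties the velocity field must not
        depend on the volume-fraction distribution."""
        from dataclasses import replace

        from etflow.cases import _FaceProvider
        from etflow.geometry import build_geometry, build_mesh

        c = builtin_case(7, withdrawal=False)
        c.phase1 = FluidPhase(rho=1259.9, mu=0.799)   # equal to phase 2
        mesh = build_mesh(build_geometry(c.geometry), h=c.h)

        def run(fill_bore: bool):
            sol = FlowSolver(mesh, c.phase1, c.phase2,
                             replace(c.solver), _FaceProvider(mesh, c))
            if fill_bore:
                sol.alpha[mesh.bore_mask(0.0)] = 1.0
            for _ in range(60):
                sol.step()
            return sol

        a = run(True)
        b = run(False)
        scale = np.abs(a.u).max()
        assert np.abs(a.u - b.u).max() / scale < 1e-8
        assert np.abs(a.v - b.v).max() / scale < 1e-8
        assert not np.allclose(a.alpha, b.alpha)   # alpha itself differs


class TestMovingCatheterBoundary:
    def test_catheter_faces_carry_withdrawal_velocity(self):
        from etflow.geometry import KIND_WALL, build_geometry, build_mesh
        m = build_mesh(build_geometry(), h=1.0)
        speed = 16.2
        fs = m.face_set(10.0, speed, 0.0)
        wall_band = (m.yc_mm > 0.3) & (m.yc_mm < 0.4)
        jj, _ = np.nonzero(fs.is_fluid)
        moving = fs.b_uw < -1e-6
        assert moving.any()
        assert np.allclose(fs.b_uw[moving], -speed * 1e-3)
        assert (fs.b_kind[moving] != 2).all()   # never on pressure faces
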