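"""Incompressible laminar homogeneous-mixture flow solver.

The transferred medium (phase 1) and the uterine fluid (phase 2) share one
local velocity field; composition is tracked by the transferred-medium
volume fraction ``alpha``.  Mixture density and viscosity are the linear
blends ``rho_m = alpha*rho1 + (1-alpha)*rho2`` and likewise for ``mu_m``.
Because both phases are incompressible and alpha is advected by the mixture
velocity, the velocity field is divergence free.

Discretisation: finite volumes on a colocated tensor-product grid, first
order upwind convection, first order implicit time stepping, SIMPLE
pressure–velocity coupling with Rhie–Chow momentum interpolation for the
face fluxes.  The volume fraction is advected with implicit upwind fluxes
(monotone, hence bounded) and clipped to [0, 1] against round-off.

All quantities are SI (m, s, kg, Pa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import (
    KIND_FLUX,
    KIND_PRESSURE,
    KIND_SYMMETRY,
    KIND_WALL,
    FaceSet,
    TensorMesh,
)

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """SIMPLE inner iterations failed to reach the continuity tolerance."""

    def __init__(self, msg: str, history: list[float]):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class FluidPhase:
    """One species of the mixture: density (kg/m^3) and viscosity (Pa s)."""

    rho: float
    mu: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")


def mixture_properties(alpha, phase1: FluidPhase, phase2: FluidPhase):
    """Linear mixture density and viscosity for volume fraction ``alpha``."""
    a = np.asarray(alpha, float)
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("volume fraction outside [0, 1]")
    a = np.clip(a, 0.0, 1.0)
    rho = a * phase1.rho + (1.0 - a) * phase2.rho
    mu = a * phase1.mu + (1.0 - a) * phase2.mu
    return rho, mu


def inlet_velocity(injected_volume_uL: float, injection_time_s: float,
                   inner_radius_mm: float) -> float:
    """Mean (plug) injection speed in mm/s through the circular bore.

    The transferred volume passes through the bore cross-section
    ``pi * r_c^2`` at a constant rate over the injection time.
    """
    if injection_time_s <= 0 or inner_radius_mm <= 0:
        raise ValueError("injection time and radius must be positive")
    if injected_volume_uL < 0:
        raise ValueError("injected volume must be non-negative")
    vol_m3 = injected_volume_uL * 1e-9
    area = np.pi * (inner_radius_mm * 1e-3) ** 2
    return vol_m3 / (injection_time_s * area) * 1e3  # mm/s


@dataclass
class SolverSettings:
    """Numerical knobs of the segregated solver.

    ``dt`` defaults to the printed 1e-4 s; the implicit scheme is stable at
    much larger steps, which the case presets use for desk-scale runs.
    Discrete continuity is enforced to round-off every outer iteration by a
    direct pressure-correction solve; ``tol`` bounds the remaining
    momentum--pressure mismatch (the pre-correction flux imbalance relative
    to the boundary inflow) at which the outer loop stops.
    """

    dt: float = 1e-4
    relax_u: float = 0.7
    relax_p: float = 0.3
    tol: float = 1e-4
    max_inner: int = 250
    rebuild_iters: int = 2
    rebuild_every: int = 25
    snapshot_every: int = 100
    transposed_stress: bool = False
    on_nonconverged: str = "raise"   # or "warn"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tol <= 0:
            raise ValueError("dt and tol must be positive")


@dataclass
class FlowField:
    """Cell-centred snapshot of the mixture flow at one instant."""

    t: float
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    alpha: np.ndarray
    rho_m: np.ndarray
    mu_m: np.ndarray
    is_fluid: np.ndarray
    continuity_residual: float


@dataclass
class Budget:
    """Cumulative volume accounting of the transferred medium (2D, m^2)."""

    influx: float = 0.0
    outflux: float = 0.0
    by_label: dict = field(default_factory=dict)

    def add(self, label: str, amount: float) -> None:
        self.by_label[label] = self.by_label.get(label, 0.0) + amount


class FlowSolver:
    """Advance the mixture flow on a blanked tensor mesh.

    ``face_provider(t)`` returns the :class:`FaceSet` (mask + BCs) valid at
    time ``t``; a new object signals a mask/BC change and triggers a remap.
    """

    def __init__(
        self,
        mesh: TensorMesh,
        phase1: FluidPhase,
        phase2: FluidPhase,
        settings: SolverSettings,
        face_provider,
    ):
        self.mesh = mesh
        self.phase1 = phase1
        self.phase2 = phase2
        self.s = settings
        self.face_provider = face_provider

        self.t = 0.0
        ny, nx = mesh.ny, mesh.nx
        self.u = np.zeros((ny, nx))
        self.v = np.zeros((ny, nx))
        self.p = np.zeros((ny, nx))
        self.alpha = np.zeros((ny, nx))
        self.solid_velocity = 0.0      # x-velocity assigned to blanked cells

        self.fs: FaceSet = face_provider(0.0)
        self._init_fluxes()
        self.budget = Budget()
        self.clip_total = 0.0
        self.last_residual = 0.0
        self._vol0 = None

    # ------------------------------------------------------------------ util
    def _flat(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.fs.is_fluid]

    def _cellV(self) -> np.ndarray:
        return self.mesh.cell_area[self.fs.is_fluid]

    def _init_fluxes(self) -> None:
        fs = self.fs
        uf = self._flat(self.u)
        vf = self._flat(self.v)
        w = fs.int_w
        vel = np.where(fs.int_dir == 0, w * uf[fs.int_P] + (1 - w) * uf[fs.int_N],
                       w * vf[fs.int_P] + (1 - w) * vf[fs.int_N])
        self.Qi = fs.int_A * vel
        self.Qb = fs.b_Q.copy()
        pres = fs.b_kind == KIND_PRESSURE
        vcell = np.where(fs.b_dir == 0, uf[fs.b_cell], vf[fs.b_cell])
        self.Qb[pres] = fs.b_A[pres] * vcell[pres]

    def _remap(self, fs_new: FaceSet) -> None:
        """Carry fields over a mask change; fill newly unblanked cells from
        their fluid neighbours."""
        old = self.fs.is_fluid
        new = fs_new.is_fluid
        fresh = new & ~old
        if fresh.any():
            for grid, default in ((self.alpha, None), (self.p, None),
                                  (self.u, self.solid_velocity), (self.v, 0.0)):
                src = np.where(old, grid, np.nan)
                for j, i in zip(*np.nonzero(fresh)):
                    nb = []
                    for jj, ii in ((j - 1, i), (j + 1, i), (j, i - 1), (j, i + 1)):
                        if 0 <= jj < src.shape[0] and 0 <= ii < src.shape[1] \
                                and np.isfinite(src[jj, ii]):
                            nb.append(src[jj, ii])
                    if nb:
                        grid[j, i] = float(np.mean(nb))
                    elif default is not None:
                        grid[j, i] = default
        self.fs = fs_new
        self._init_fluxes()

    # ------------------------------------------------------------ assembly
    def _gradient(self, pf: np.ndarray, dirichlet0: bool = False) -> tuple:
        """Green–Gauss cell gradient of a flat scalar.  Pressure-kind faces
        use their fixed value (0 for the correction when ``dirichlet0``),
        every other boundary face uses the zero-normal-gradient value."""
        fs = self.fs
        V = self._cellV()
        gx = np.zeros(fs.n)
        gy = np.zeros(fs.n)
        w = fs.int_w
        face_p = w * pf[fs.int_P] + (1 - w) * pf[fs.int_N]
        contrib = fs.int_A * face_p
        for d, g in ((0, gx), (1, gy)):
            m = fs.int_dir == d
            np.add.at(g, fs.int_P[m], contrib[m])
            np.add.at(g, fs.int_N[m], -contrib[m])
        bp = pf[fs.b_cell].copy()
        pres = fs.b_kind == KIND_PRESSURE
        bp[pres] = 0.0 if dirichlet0 else fs.b_p0[pres]
        bc = fs.b_side * fs.b_A * bp
        for d, g in ((0, gx), (1, gy)):
            m = fs.b_dir == d
            np.add.at(g, fs.b_cell[m], bc[m])
        return gx / V, gy / V

    def _transposed_stress(self, mu_grid: np.ndarray) -> tuple:
        """Explicit source from the transposed-gradient part of the stress.

        For a divergence-free field ``div(mu grad(u)^T)`` reduces exactly to
        ``(grad mu) . grad(u_j)`` per component, which contains only first
        derivatives and is therefore stable as an explicit source; it
        vanishes identically for uniform viscosity.
        """
        xc, yc = self.mesh.xc, self.mesh.yc
        u, v = self.u, self.v

        def dgx(f):
            return np.gradient(f, xc, axis=1)

        def dgy(f):
            return np.gradient(f, yc, axis=0)

        mx = dgx(mu_grid)
        my = dgy(mu_grid)
        tu = mx * dgx(u) + my * dgx(v)
        tv = mx * dgy(u) + my * dgy(v)
        return self._flat(tu), self._flat(tv)

    def _assemble_momentum(self, rho, mu, rho_grid_unused=None):
        """Matrix pieces shared by both velocity components plus per
        component boundary diagonals and RHS boundary sources."""
        fs = self.fs
        V = self._cellV()
        dt = self.s.dt

        diag = rho * V / dt
        rows, cols, vals = [], [], []
        diag_add = np.zeros(fs.n)

        w = fs.int_w
        mu_f = w * mu[fs.int_P] + (1 - w) * mu[fs.int_N]
        D = mu_f * fs.int_A / fs.int_delta
        rho_up = np.where(self.Qi > 0, rho[fs.int_P], rho[fs.int_N])
        F = rho_up * self.Qi
        aP_side = D + np.maximum(F, 0.0)
        aN_side = D + np.maximum(-F, 0.0)
        np.add.at(diag_add, fs.int_P, aP_side)
        np.add.at(diag_add, fs.int_N, aN_side)
        rows.append(fs.int_P); cols.append(fs.int_N); vals.append(-aN_side)
        rows.append(fs.int_N); cols.append(fs.int_P); vals.append(-aP_side)

        diag_u = np.zeros(fs.n)
        diag_v = np.zeros(fs.n)
        src_u = np.zeros(fs.n)
        src_v = np.zeros(fs.n)

        c = fs.b_cell
        Dw = mu[c] * fs.b_A / fs.b_dh
        out = fs.b_side * self.Qb            # outward volume flux
        Fout = rho[c] * out
        Fin = np.maximum(-Fout, 0.0)

        wall = fs.b_kind == KIND_WALL
        np.add.at(diag_u, c[wall], Dw[wall])
        np.add.at(diag_v, c[wall], Dw[wall])
        np.add.at(src_u, c[wall], Dw[wall] * fs.b_uw[wall])
        np.add.at(src_v, c[wall], Dw[wall] * fs.b_vw[wall])

        sym = fs.b_kind == KIND_SYMMETRY
        np.add.at(diag_v, c[sym], Dw[sym])   # normal component pinned to 0

        conv = wall | (fs.b_kind == KIND_PRESSURE) | (fs.b_kind == KIND_FLUX)
        np.add.at(diag_u, c[conv], np.maximum(Fout[conv], 0.0))
        np.add.at(diag_v, c[conv], np.maximum(Fout[conv], 0.0))
        carry = wall | (fs.b_kind == KIND_FLUX)
        np.add.at(src_u, c[carry], Fin[carry] * fs.b_uw[carry])
        np.add.at(src_v, c[carry], Fin[carry] * fs.b_vw[carry])

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        base = diag + diag_add
        return rows, cols, vals, base, diag_u, diag_v, src_u, src_v

    def _face_flux(self, uf, vf, pf, d_u, d_v, gx, gy):
        """Rhie–Chow volume fluxes on internal and pressure-boundary faces."""
        fs = self.fs
        w = fs.int_w
        isx = fs.int_dir == 0
        vel = np.where(isx, w * uf[fs.int_P] + (1 - w) * uf[fs.int_N],
                       w * vf[fs.int_P] + (1 - w) * vf[fs.int_N])
        dP = np.where(isx, d_u[fs.int_P], d_v[fs.int_P])
        dN = np.where(isx, d_u[fs.int_N], d_v[fs.int_N])
        dbar = w * dP + (1 - w) * dN
        gbar = np.where(isx, w * gx[fs.int_P] + (1 - w) * gx[fs.int_N],
                        w * gy[fs.int_P] + (1 - w) * gy[fs.int_N])
        dpdn = (pf[fs.int_N] - pf[fs.int_P]) / fs.int_delta
        Qi = fs.int_A * (vel - dbar * (dpdn - gbar))

        Qb = fs.b_Q.copy()
        pres = fs.b_kind == KIND_PRESSURE
        if pres.any():
            c = fs.b_cell[pres]
            d = fs.b_dir[pres]
            side = fs.b_side[pres]
            vcell = np.where(d == 0, uf[c], vf[c])
            dcell = np.where(d == 0, d_u[c], d_v[c])
            gcell = np.where(d == 0, gx[c], gy[c])
            dpdn_b = side * (fs.b_p0[pres] - pf[c]) / fs.b_dh[pres]
            Qb[pres] = fs.b_A[pres] * (vcell - dcell * (dpdn_b - gcell))
        return Qi, Qb, dbar

    def _divergence(self, Qi, Qb):
        fs = self.fs
        div = np.zeros(fs.n)
        np.add.at(div, fs.int_P, Qi)
        np.add.at(div, fs.int_N, -Qi)
        np.add.at(div, fs.b_cell, fs.b_side * Qb)
        return div

    def _inflow_scale(self) -> float:
        """Flux scale for the relative continuity residual: the prescribed
        boundary inflow when present, else the largest face flux."""
        out = self.fs.b_side * self.Qb
        inflow = float(np.maximum(-out, 0.0).sum())
        return max(inflow, float(np.abs(self.Qi).max(initial=0.0)),
                   float(np.abs(self.Qb).max(initial=0.0)), 1e-300)

    # ------------------------------------------------------------- stepping
    def step(self) -> None:
        """Advance one implicit time step (SIMPLE loop, then alpha)."""
        s = self.s
        t_new = self.t + s.dt
        fs_new = self.face_provider(t_new)
        if fs_new is not self.fs:
            self._remap(fs_new)
        fs = self.fs
        V = self._cellV()

        rho_grid, mu_grid = mixture_properties(self.alpha, self.phase1, self.phase2)
        rho = rho_grid[fs.is_fluid]
        mu = mu_grid[fs.is_fluid]

        uf = self._flat(self.u)
        vf = self._flat(self.v)
        pf = self._flat(self.p)
        rhs_u0 = rho * V / s.dt * uf
        rhs_v0 = rho * V / s.dt * vf
        if s.transposed_stress:
            tu, tv = self._transposed_stress(mu_grid)
            rhs_u0 = rhs_u0 + V * tu
            rhs_v0 = rhs_v0 + V * tv

        u, v, p = uf.copy(), vf.copy(), pf.copy()
        Qref = self._inflow_scale()
        history: list[float] = []
        lu_u = lu_v = lu_p = None
        res = np.inf
        for it in range(s.max_inner):
            if it < s.rebuild_iters or it % s.rebuild_every == 0:
                rows, cols, vals, base, diag_u, diag_v, src_u, src_v = \
                    self._assemble_momentum(rho, mu)
                aP_u = base + diag_u
                aP_v = base + diag_v
                d_u = V / aP_u
                d_v = V / aP_v
                Au = sp.csc_matrix(
                    (np.concatenate([vals, aP_u / s.relax_u]),
                     (np.concatenate([rows, np.arange(fs.n)]),
                      np.concatenate([cols, np.arange(fs.n)]))),
                    shape=(fs.n, fs.n))
                Av = sp.csc_matrix(
                    (np.concatenate([vals, aP_v / s.relax_u]),
                     (np.concatenate([rows, np.arange(fs.n)]),
                      np.concatenate([cols, np.arange(fs.n)]))),
                    shape=(fs.n, fs.n))
                lu_u = splu(Au)
                lu_v = splu(Av)
                lu_p = None

            gx, gy = self._gradient(p)
            relax = (1.0 - s.relax_u) / s.relax_u
            u = lu_u.solve(rhs_u0 + src_u - V * gx + relax * aP_u * u)
            v = lu_v.solve(rhs_v0 + src_v - V * gy + relax * aP_v * v)

            Qi, Qb, dbar = self._face_flux(u, v, p, d_u, d_v, gx, gy)
            self.Qi, self.Qb = Qi, Qb
            div = self._divergence(Qi, Qb)
            Qref = self._inflow_scale()
            res = float(np.abs(div).sum()) / Qref
            history.append(res)

            if lu_p is None:
                c_int = fs.int_A * dbar / fs.int_delta
                pres = fs.b_kind == KIND_PRESSURE
                cb = np.zeros(fs.b_cell.size)
                dc = np.where(fs.b_dir == 0, d_u[fs.b_cell], d_v[fs.b_cell])
                cb[pres] = fs.b_A[pres] * dc[pres] / fs.b_dh[pres]
                diag_p = np.zeros(fs.n)
                np.add.at(diag_p, fs.int_P, c_int)
                np.add.at(diag_p, fs.int_N, c_int)
                np.add.at(diag_p, fs.b_cell, cb)
                Lp = sp.csc_matrix(
                    (np.concatenate([-c_int, -c_int, diag_p]),
                     (np.concatenate([fs.int_P, fs.int_N, np.arange(fs.n)]),
                      np.concatenate([fs.int_N, fs.int_P, np.arange(fs.n)]))),
                    shape=(fs.n, fs.n))
                lu_p = splu(Lp)
                cb_pres = cb
            pc = lu_p.solve(-div)
            p = p + s.relax_p * pc
            self.Qi = Qi = Qi + c_int * (pc[fs.int_P] - pc[fs.int_N])
            corr_b = fs.b_side * cb_pres * pc[fs.b_cell]
            self.Qb = Qb = Qb + corr_b
            gpx, gpy = self._gradient(pc, dirichlet0=True)
            u = u - d_u * gpx
            v = v - d_v * gpy
            # the direct correction renders the stored fluxes divergence
            # free to round-off; ``res`` measures the momentum–pressure
            # mismatch still being iterated out
            if res < s.tol and it > 0:
                break
        else:
            msg = (f"SIMPLE did not converge at t={t_new:.4g}s: "
                   f"residual {res:.3e} after {s.max_inner} iterations")
            if s.on_nonconverged == "raise":
                raise ConvergenceError(msg, history)
            log.warning(msg)

        self.last_residual = res
        self.continuity_max = float(
            np.abs(self._divergence(self.Qi, self.Qb)).max()) / Qref
        self.u[fs.is_fluid] = u
        self.v[fs.is_fluid] = v
        self.p[fs.is_fluid] = p
        self._advect_alpha()
        self.t = t_new
        self._fill_solid()

    def _advect_alpha(self) -> None:
        """Implicit first-order upwind transport of the volume fraction."""
        fs = self.fs
        s = self.s
        V = self._cellV()
        af = self._flat(self.alpha)
        if self._vol0 is None:
            self._vol0 = float((af * V).sum())

        diag = V / s.dt
        rhs = V / s.dt * af
        Qi = self.Qi
        diag_add = np.zeros(fs.n)
        np.add.at(diag_add, fs.int_P, np.maximum(Qi, 0.0))
        np.add.at(diag_add, fs.int_N, np.maximum(-Qi, 0.0))
        rows = np.concatenate([fs.int_P, fs.int_N])
        cols = np.concatenate([fs.int_N, fs.int_P])
        vals = np.concatenate([-np.maximum(-Qi, 0.0), -np.maximum(Qi, 0.0)])

        out = fs.b_side * self.Qb
        c = fs.b_cell
        np.add.at(diag_add, c, np.maximum(out, 0.0))
        # inflow: prescribed alpha, ambient fluid (alpha=0) at pressure
        # boundaries, or zero-gradient (carries the cell's own alpha)
        given = np.isfinite(fs.b_alpha)
        pres = fs.b_kind == KIND_PRESSURE
        zg = ~given & ~pres
        inflow = np.maximum(-out, 0.0)
        np.add.at(rhs, c[given], inflow[given] * fs.b_alpha[given])
        np.add.at(diag_add, c[zg], -inflow[zg])

        M = sp.csc_matrix(
            (np.concatenate([vals, diag + diag_add]),
             (np.concatenate([rows, np.arange(fs.n)]),
              np.concatenate([cols, np.arange(fs.n)]))),
            shape=(fs.n, fs.n))
        a_new = splu(M).solve(rhs)

        clip = np.clip(a_new, 0.0, 1.0)
        clipped = float(np.abs(a_new - clip).sum())
        self.clip_total += clipped
        if clipped > 1e-10:
            log.debug("alpha clipped by %.3e at t=%.4g", clipped, self.t)
        a_new = clip
        self.alpha[fs.is_fluid] = a_new

        # budget bookkeeping (volume of transferred medium crossing faces)
        a_in = np.where(given, fs.b_alpha, np.where(pres, 0.0, a_new[c]))
        step_in = float((inflow * a_in).sum()) * s.dt
        step_out = float((np.maximum(out, 0.0) * a_new[c]).sum()) * s.dt
        self.budget.influx += step_in
        self.budget.outflux += step_out
        for lab in np.unique(fs.b_label):
            m = fs.b_label == lab
            net = float((np.maximum(out[m], 0.0) * a_new[c[m]]
                         - inflow[m] * a_in[m]).sum()) * s.dt
            self.budget.add(str(lab), net)

    def _fill_solid(self) -> None:
        """Assign wall velocities to blanked cells (used by interpolation)."""
        solid = ~self.fs.is_fluid
        self.u[solid] = self.solid_velocity
        self.v[solid] = 0.0

    # ------------------------------------------------------------- outputs
    def snapshot(self) -> FlowField:
        rho, mu = mixture_properties(self.alpha, self.phase1, self.phase2)
        return FlowField(
            t=self.t, u=self.u.copy(), v=self.v.copy(), p=self.p.copy(),
            alpha=self.alpha.copy(), rho_m=rho, mu_m=mu,
            is_fluid=self.fs.is_fluid.copy(),
            continuity_residual=self.last_residual,
        )

    def alpha_volume(self) -> float:
        """Domain integral of alpha (2D volume per unit depth, m^2)."""
        return float((self._flat(self.alpha) * self._cellV()).sum())

    def mass_budget_error(self) -> float:
        """|stored - injected + outflux| relative to the total influx."""
        stored = self.alpha_volume() - (self._vol0 or 0.0)
        if self.budget.influx <= 0:
            return abs(stored + self.budget.outflux)
        return abs(stored + self.budget.outflux - self.budget.influx) \
            / self.budget.influx

    def boundary_pressure(self, label: str) -> float:
        """Area-weighted mean gauge pressure on faces with a given tag."""
        fs = self.fs
        m = fs.b_label == label
        if not m.any():
            return 0.0
        pf = self._flat(self.p)[fs.b_cell[m]]
        return float((pf * fs.b_A[m]).sum() / fs.b_A[m].sum())
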