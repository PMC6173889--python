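"""Lagrangian embryo tracking through the mixture flow.

Each embryo is a small rigid sphere whose only force is quasi-steady drag
against the local mixture velocity:

    dv_e/dt = beta * (u_m - v_e),        dx_e/dt = v_e

with the drag coefficient from the piecewise Morsi–Alexander correlation
C_D(Re_r) = a1 + a2/Re_r + a3/Re_r^2 and the relative Reynolds number
Re_r = 2 rho_m r_e |v_e - u_m| / mu_m.  The embryo does not act back on the
flow and embryos do not interact, so the ten trajectories are independent.

The drag term is extremely stiff for these parameters (relaxation times of
microseconds), so the velocity is integrated exactly over each step with
the local fluid velocity frozen (exponential update); the displacement then
follows by the trapezoidal rule.  Two drag prefactors are selectable:
``standard`` (Stokes limit 9 mu / (2 rho_e r_e^2), the conventional
particle-drag response) and ``paper`` (exactly twice that); with these
parameters both collapse to the tracer limit, see docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

#: Morsi–Alexander bands: (Re upper bound, a1, a2, a3)
MORSI_ALEXANDER = (
    (0.1, 0.0, 24.0, 0.0),
    (1.0, 3.690, 22.73, 0.0903),
    (10.0, 1.222, 29.1667, -3.8889),
    (100.0, 0.6167, 46.50, -116.67),
    (1000.0, 0.3644, 98.33, -2778.0),
    (5000.0, 0.357, 148.62, -47500.0),
    (10000.0, 0.46, -490.546, 578700.0),
    (np.inf, 0.5191, -1662.5, 5416700.0),
)

STATUSES = ("in_catheter", "downstream", "upstream", "exited_cervix", "exited_tube")


@dataclass(frozen=True)
class EmbryoParams:
    """Spherical embryo: radius and density, plus the loading position."""

    radius: float = 0.05e-3        # m  (d_e = 0.1 mm)
    density: float = 1000.0        # kg/m^3
    tip_distance: float = 10e-3    # m, initial axial distance behind the tip

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0 or self.tip_distance < 0:
            raise ValueError("embryo parameters must be positive")


def initial_positions(r_c: float, r_e: float) -> np.ndarray:
    """Radial start offsets of the ten embryos (same units as the inputs).

    The catheter cross-section is split into ten equal-area zones by the
    circles ``r_i = sqrt(i/10) (r_c - r_e)``; each embryo centre sits at the
    midpoint of its radial segment, ``y_i = (r_{i-1} + r_i) / 2``.
    """
    if not 0 < r_e < r_c:
        raise ValueError("embryo radius must be positive and below the bore radius")
    i = np.arange(0, 11)
    r = np.sqrt(i / 10.0) * (r_c - r_e)
    return 0.5 * (r[:-1] + r[1:])


def relative_reynolds(rho_m, mu_m, r_e, v_e, u_m):
    """Slip Reynolds number ``2 rho_m r_e |v_e - u_m| / mu_m``."""
    slip = np.linalg.norm(np.asarray(v_e, float) - np.asarray(u_m, float), axis=-1)
    return 2.0 * rho_m * r_e * slip / mu_m


def drag_coefficient(re_r: float) -> float:
    """Sphere drag coefficient from the Morsi–Alexander bands (Re_r > 0)."""
    if re_r < 0:
        raise ValueError("relative Reynolds number must be non-negative")
    if re_r == 0.0:
        return np.inf  # Stokes limit: C_D * Re -> 24 (handled in drag_response)
    for hi, a1, a2, a3 in MORSI_ALEXANDER:
        if re_r <= hi:
            return a1 + a2 / re_r + a3 / re_r**2
    raise AssertionError("unreachable")


def _cd_re(re_r: float) -> float:
    """The product C_D * Re_r, finite for Re_r -> 0 (-> 24)."""
    if re_r <= 1e-12:
        return 24.0
    return drag_coefficient(re_r) * re_r


def drag_response(mu_m: float, rho_m: float, c_d: float, re_r: float,
                  embryo: EmbryoParams, form: str = "standard") -> float:
    """Inverse velocity-relaxation time beta (1/s) multiplying (u_m - v_e).

    ``standard``: beta = 3 mu C_D Re_r / (16 rho_e r_e^2), whose Stokes
    limit is 9 mu / (2 rho_e r_e^2); ``paper`` is exactly twice that.
    """
    cdre = c_d * re_r if np.isfinite(c_d) else 24.0
    if form == "standard":
        return 3.0 * mu_m * cdre / (16.0 * embryo.density * embryo.radius**2)
    if form == "paper":
        return 3.0 * mu_m * cdre / (8.0 * embryo.density * embryo.radius**2)
    raise ValueError(f"unknown drag form: {form!r}")


@dataclass
class EmbryoState:
    """Position (m), velocity (m/s) and region status of one embryo."""

    id: int
    x: float
    y: float
    vx: float = 0.0
    vy: float = 0.0
    status: str = "in_catheter"

    @property
    def frozen(self) -> bool:
        return self.status in ("exited_cervix", "exited_tube")


@dataclass
class Trajectory:
    """Recorded time history of one embryo at the snapshot cadence."""

    id: int
    times: list = field(default_factory=list)
    states: list = field(default_factory=list)

    def record(self, t: float, state: EmbryoState) -> None:
        if self.times and t <= self.times[-1]:
            return
        self.times.append(t)
        self.states.append(replace(state))

    def at(self, t: float) -> EmbryoState:
        """State at the recorded instant nearest ``t``."""
        i = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        return self.states[i]


def step_embryo(state: EmbryoState, u_m, rho_m: float, mu_m: float,
                dt: float, params: EmbryoParams, form: str = "standard"
                ) -> EmbryoState:
    """One time step: exponential velocity update, trapezoidal displacement."""
    if state.frozen:
        return state
    v_old = np.array([state.vx, state.vy])
    u = np.asarray(u_m, float)
    re_r = relative_reynolds(rho_m, mu_m, params.radius, v_old, u)
    beta = drag_response(mu_m, rho_m, np.inf if re_r == 0 else drag_coefficient(re_r),
                         re_r, params, form)
    decay = np.exp(-beta * dt) if beta * dt < 700 else 0.0
    v_new = u + (v_old - u) * decay
    dxy = 0.5 * dt * (v_old + v_new)
    return replace(state, x=state.x + dxy[0], y=state.y + dxy[1],
                   vx=v_new[0], vy=v_new[1])


class EmbryoTracker:
    """Track the ten embryos through a live solver run.

    The local flow is sampled at the embryo position by bilinear
    interpolation from cell centres; blanked cells hold the wall velocity so
    near-wall samples relax toward the no-slip value.  Embryos that land in
    a blanked cell are pushed back to the nearest fluid cell centre and the
    event is counted.
    """

    def __init__(self, solver, outline, params: EmbryoParams,
                 form: str = "standard"):
        self.solver = solver
        self.outline = outline
        self.params = params
        self.form = form
        g = outline.params
        r_c = g.r_c * 1e-3
        offsets = initial_positions(r_c, params.radius)
        x0 = g.tip_x * 1e-3 - params.tip_distance
        self.states = [EmbryoState(id=k + 1, x=x0, y=float(yk))
                       for k, yk in enumerate(offsets)]
        self.trajectories = [Trajectory(id=s.id) for s in self.states]
        self.pushback_count = 0
        self._tree = None
        self._tree_fs = None
        for tr, s in zip(self.trajectories, self.states):
            tr.record(0.0, s)

    def _interpolator(self):
        mesh = self.solver.mesh
        vals = np.stack([self.solver.u, self.solver.v], axis=-1)
        p1, p2 = self.solver.phase1, self.solver.phase2
        a = self.solver.alpha
        rho_m = a * p1.rho + (1 - a) * p2.rho
        mu_m = a * p1.mu + (1 - a) * p2.mu
        vals = np.concatenate([vals, rho_m[..., None], mu_m[..., None]], axis=-1)
        return RegularGridInterpolator((mesh.yc, mesh.xc), vals,
                                       bounds_error=False, fill_value=None)

    def _fluid_tree(self):
        fs = self.solver.fs
        if self._tree is None or self._tree_fs is not fs:
            mesh = self.solver.mesh
            jj, ii = np.nonzero(fs.is_fluid)
            self._tree = cKDTree(np.column_stack([mesh.yc[jj], mesh.xc[ii]]))
            self._pts = np.column_stack([mesh.yc[jj], mesh.xc[ii]])
            self._tree_fs = fs
        return self._tree

    def _classify(self, s: EmbryoState, tip_x_now: float) -> str:
        g = self.outline.params
        mm = 1e-3
        if s.x < 0.0:
            return "exited_cervix"
        y0, y1 = self.outline.tube_ostium
        if s.x >= (g.fundus_x - 0.05) * mm and s.y >= y0 * mm:
            return "exited_tube"
        entry_now = tip_x_now - g.catheter_length_in_cavity * mm
        if entry_now < s.x <= tip_x_now and abs(s.y) < g.r_c * mm \
                and tip_x_now > 0:
            return "in_catheter"
        return "downstream" if s.x > g.tip_x * mm else "upstream"

    def step(self, tip_x_now_m: float) -> None:
        """Advance all embryos over the solver's current time step."""
        interp = self._interpolator()
        mesh = self.solver.mesh
        dt = self.solver.s.dt
        for k, s in enumerate(self.states):
            if s.frozen:
                continue
            yq = np.clip(s.y, mesh.yc[0], mesh.yc[-1])
            xq = np.clip(s.x, mesh.xc[0], mesh.xc[-1])
            u, v, rho_m, mu_m = interp((yq, xq))
            new = step_embryo(s, (u, v), float(rho_m), float(mu_m),
                              dt, self.params, self.form)
            # geometric pushback if the embryo ended up in a blanked cell
            j = int(np.clip(np.searchsorted(mesh.yf, new.y) - 1, 0, mesh.ny - 1))
            i = int(np.clip(np.searchsorted(mesh.xf, new.x) - 1, 0, mesh.nx - 1))
            inside = (0 <= new.y <= mesh.yf[-1]) and (0 <= new.x <= mesh.xf[-1])
            if new.x >= 0 and (not inside or not self.solver.fs.is_fluid[j, i]):
                tree = self._fluid_tree()
                _, idx = tree.query([new.y, new.x])
                new = replace(new, y=float(self._pts[idx][0]),
                              x=float(self._pts[idx][1]))
                self.pushback_count += 1
                log.debug("embryo e%d pushed back to fluid at t=%.4g",
                          new.id, self.solver.t)
            new = replace(new, status=self._classify(new, tip_x_now_m))
            self.states[k] = new

    def record(self, t: float) -> None:
        for tr, s in zip(self.trajectories, self.states):
            tr.record(t, s)


def track_all(solver, outline, t_end: float,
              params: EmbryoParams | None = None,
              form: str = "standard",
              tip_x_fn=None) -> list[Trajectory]:
    """Advance a live flow solver to ``t_end`` while tracking the ten
    embryos; returns their trajectories (recorded at the snapshot cadence).

    Each embryo is advanced independently through the same flow (no
    embryo–embryo coupling and no back-reaction on the flow).
    ``tip_x_fn(t)`` supplies the current catheter-tip position in metres
    (defaults to the resting tip).
    """
    params = params or EmbryoParams()
    tracker = EmbryoTracker(solver, outline, params, form)
    tip0 = outline.tip_x * 1e-3
    k = 0
    while solver.t < t_end - 1e-12:
        solver.step()
        tracker.step(tip_x_fn(solver.t) if tip_x_fn else tip0)
        k += 1
        if k % solver.s.snapshot_every == 0:
            tracker.record(solver.t)
    tracker.record(solver.t)
    return tracker.trajectories
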