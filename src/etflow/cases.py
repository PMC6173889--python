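"""Study cases and orchestration: embryo injection followed by catheter
withdrawal.

The nine built-in cases sweep the transferred-medium viscosity from normal
saline (0.001 Pa s) up to the uterine-fluid value (0.799 Pa s) at fast
(1 s) and slow (15 s) injection of a fixed 20 uL load; case 1 is the
reference (saline) case and case 7 the equal-viscosity case.  Withdrawal
(5 s, constant speed) is simulated for the reference and equal-viscosity
cases by default.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .embryos import EmbryoParams, EmbryoTracker
from .flow import FlowSolver, FluidPhase, SolverSettings, inlet_velocity
from .geometry import (
    MM,
    UterusGeometry,
    WithdrawalProtocol,
    build_geometry,
    build_mesh,
    catheter_position,
)

log = logging.getLogger(__name__)

#: (viscosity Pa s, density kg/m^3, injection time s) for cases 1..9
TABLE1 = {
    1: (0.001, 1000.0, 1.0),
    2: (0.005, 1001.3, 1.0),
    3: (0.01, 1002.9, 1.0),
    4: (0.05, 1016.0, 1.0),
    5: (0.1, 1032.2, 1.0),
    6: (0.5, 1162.5, 1.0),
    7: (0.799, 1259.9, 1.0),
    8: (0.001, 1000.0, 15.0),
    9: (0.799, 1259.9, 15.0),
}

UTERINE_FLUID = FluidPhase(rho=1259.9, mu=0.799)


@dataclass
class CaseConfig:
    """Full parameterisation of one simulation case."""

    case_index: int | None
    phase1: FluidPhase
    phase2: FluidPhase = UTERINE_FLUID
    injected_volume_uL: float = 20.0
    t_inj: float = 1.0
    withdrawal: WithdrawalProtocol = field(
        default_factory=lambda: WithdrawalProtocol(enabled=False))
    geometry: UterusGeometry = field(default_factory=UterusGeometry)
    solver: SolverSettings = field(default_factory=SolverSettings)
    dt_withdrawal: float | None = None   # defaults to 2.5x the injection dt
    embryo: EmbryoParams = field(default_factory=EmbryoParams)
    drag_form: str = "standard"
    h: float = 1.0            # coarse mesh spacing, mm
    fine: float = 0.1         # near-axis spacing, mm
    tip_refine: float = 0.5   # spacing near the catheter tip, mm

    @property
    def inlet_speed_mm_s(self) -> float:
        return inlet_velocity(self.injected_volume_uL, self.t_inj,
                              self.geometry.r_c)

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["phase1"] = FluidPhase(**d["phase1"])
        d["phase2"] = FluidPhase(**d["phase2"])
        d["withdrawal"] = WithdrawalProtocol(**d["withdrawal"])
        d["geometry"] = UterusGeometry(**d["geometry"])
        d["solver"] = SolverSettings(**d["solver"])
        d["embryo"] = EmbryoParams(**d["embryo"])
        return cls(**d)


def builtin_case(i: int, *, withdrawal: bool | None = None,
                 h: float = 1.0) -> CaseConfig:
    """The exact tabulated parameterisation of case ``i`` (1..9).

    Withdrawal is enabled by default for the reference (1) and
    equal-viscosity (7) cases only.  Desk-scale solver presets (implicit
    time steps of 1 ms for fast injection, 5 ms for slow) are applied; the
    mesh resolution ``h`` is a free parameter.
    """
    if i not in TABLE1:
        raise ValueError(f"case index must be 1..9, got {i}")
    mu1, rho1, t_inj = TABLE1[i]
    wd = withdrawal if withdrawal is not None else i in (1, 7)
    dt = 1e-3 if t_inj <= 1.0 else 5e-3
    return CaseConfig(
        case_index=i,
        phase1=FluidPhase(rho=rho1, mu=mu1),
        t_inj=t_inj,
        withdrawal=WithdrawalProtocol(enabled=wd, start_time=t_inj),
        solver=SolverSettings(dt=dt),
        dt_withdrawal=2.5e-3,
        h=h,
    )


@dataclass
class RunResult:
    """Everything one simulation produced; summaries are recomputable from
    the stored trajectories and snapshots."""

    config: CaseConfig
    mesh: object
    snapshots: list
    trajectories: list
    summary: metrics.TransportSummary
    pattern: metrics.DispersionPattern
    force_series: pd.DataFrame       # t, inlet_pressure_Pa, force_N
    budget_log: pd.DataFrame
    mass_budget_error: float             # at the end of the whole run
    mass_budget_error_injection: float   # at the end of injection
    pushback_count: int
    config_hash: str


class _FaceProvider:
    """Time-dependent mask/BC provider with caching on the discrete state."""

    def __init__(self, mesh, config: CaseConfig):
        self.mesh = mesh
        self.c = config
        self.u_in = config.inlet_speed_mm_s * MM  # m/s
        self._key = None
        self._fs = None
        self.offset = 0.0
        self.speed = 0.0

    def regime(self, t: float) -> str:
        if t <= self.c.t_inj + 1e-12:
            return "inject"
        offset, speed = catheter_position(t, self.c.withdrawal)
        self.offset, self.speed = offset, speed
        return "withdraw" if speed > 0 else "closed"

    def __call__(self, t: float):
        reg = self.regime(t)
        if reg == "inject":
            self.offset, self.speed = 0.0, 0.0
        key = self.mesh.mask_key(self.offset, reg)
        if key != self._key:
            self._fs = self.mesh.face_set(
                self.offset, self.speed, self.u_in if reg == "inject" else 0.0)
            self._key = key
        return self._fs


def run_case(config: CaseConfig, progress: bool = False) -> RunResult:
    """Simulate injection (and optionally withdrawal) and track embryos.

    Initial condition: catheter bore filled with transferred medium
    (alpha = 1), cavity with uterine fluid (alpha = 0), everything at rest.
    Deterministic for a given configuration.
    """
    g = config.geometry
    outline = build_geometry(g)
    mesh = build_mesh(outline, h=config.h, fine=config.fine,
                      tip_refine=config.tip_refine)

    provider = _FaceProvider(mesh, config)
    solver = FlowSolver(mesh, config.phase1, config.phase2,
                        replace(config.solver), provider)
    solver.alpha[mesh.bore_mask(0.0)] = 1.0

    tracker = EmbryoTracker(solver, outline, config.embryo, config.drag_form)

    snapshots = []
    force_rows = []
    budget_rows = []
    r_c_mm = g.r_c

    def tip_x_now() -> float:
        return (g.tip_x - provider.offset) * MM

    def do_phase(t_end: float, dt: float, inject: bool) -> None:
        solver.s.dt = dt
        nsteps = max(1, round((t_end - solver.t) / dt))
        solver.s.dt = (t_end - solver.t) / nsteps
        for k in range(nsteps):
            try:
                solver.step()
            except Exception:
                log.error("solver failure in case %s at t=%.4g s",
                          config.case_index, solver.t)
                raise
            solver.solid_velocity = -provider.speed * MM
            solver._fill_solid()
            tracker.step(tip_x_now())
            if inject:
                p_in = solver.boundary_pressure("INLET")
                force_rows.append((solver.t, p_in,
                                   metrics.driving_force(p_in, r_c_mm)))
            if (k + 1) % solver.s.snapshot_every == 0 or k == nsteps - 1:
                snapshots.append(solver.snapshot())
                tracker.record(solver.t)
                budget_rows.append((solver.t, solver.budget.influx,
                                    solver.budget.outflux,
                                    solver.alpha_volume(),
                                    solver.last_residual))
                if progress:
                    log.info("case %s t=%.3f s res=%.2e", config.case_index,
                             solver.t, solver.last_residual)

    do_phase(config.t_inj, config.solver.dt, inject=True)
    tracker.record(solver.t)
    t_ref = solver.t
    budget_err_inj = solver.mass_budget_error()
    pattern = metrics.dispersion_contour(solver.snapshot(), mesh,
                                         tip_x_mm=g.tip_x, r_oc_mm=g.r_oc)

    if config.withdrawal.enabled:
        dt_w = config.dt_withdrawal or 2.5 * config.solver.dt
        do_phase(config.t_inj + config.withdrawal.duration, dt_w, inject=False)
        tracker.record(solver.t)

    summary = metrics.transport_distances(tracker.trajectories, g.tip_x,
                                          t_ref, config.case_index)
    force = pd.DataFrame(force_rows, columns=["t", "inlet_pressure_Pa",
                                              "force_N"])
    summary.driving_force_N = float(force["force_N"].mean()) if len(force) else None
    if config.withdrawal.enabled:
        back, exited = metrics.withdrawal_dragback(
            tracker.trajectories, t_ref, solver.t)
        summary.dragback_mm = back
        summary.n_exited_cervix = exited
        summary.n_entered_cervix = sum(
            tr.at(solver.t).x / MM < g.cervix_length
            or tr.at(solver.t).status == "exited_cervix"
            for tr in tracker.trajectories)
    else:
        summary.dragback_mm = 0.0

    budget = pd.DataFrame(budget_rows, columns=[
        "t", "alpha_influx_m2", "alpha_outflux_m2", "alpha_volume_m2",
        "continuity_residual"])
    return RunResult(
        config=config, mesh=mesh, snapshots=snapshots,
        trajectories=tracker.trajectories, summary=summary, pattern=pattern,
        force_series=force, budget_log=budget,
        mass_budget_error=solver.mass_budget_error(),
        mass_budget_error_injection=budget_err_inj,
        pushback_count=tracker.pushback_count,
        config_hash=config.config_hash(),
    )
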