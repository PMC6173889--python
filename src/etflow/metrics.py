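"""Post-processing: dispersion pattern, delivery regions, transport
distances, withdrawal drag-back and the injection driving force.

Reported lengths are millimetres (axial distances positive toward the
fundus, measured from the catheter tip at rest), forces are newtons using
the circular-bore area convention ``pi r_c^2`` for the 2D planar fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage import measure

MM = 1e-3


@dataclass
class DispersionPattern:
    """The alpha = 0.5 contour of the transferred medium at one instant."""

    t: float
    contours: list          # polylines, (N, 2) arrays of (x, y) in mm
    enclosed_area: float    # mm^2, summed over closed contours
    upstream_area: float    # mm^2 of medium behind the tip, outside the catheter
    shape_class: str        # incomplete_ellipse | sector | other


def _index_to_mm(contour_rc: np.ndarray, yc_mm: np.ndarray,
                 xc_mm: np.ndarray) -> np.ndarray:
    """Map (row, col) index-space contour vertices to physical (x, y) mm."""
    rows = np.interp(contour_rc[:, 0], np.arange(yc_mm.size), yc_mm)
    cols = np.interp(contour_rc[:, 1], np.arange(xc_mm.size), xc_mm)
    return np.column_stack([cols, rows])


def dispersion_contour(field, mesh, tip_x_mm: float = 60.0,
                       r_oc_mm: float = 0.4,
                       level: float = 0.5,
                       lobe_threshold_mm2: float = 1.0) -> DispersionPattern:
    """Extract the alpha = ``level`` contour by marching squares.

    Blanked cells are excluded via NaN masking.  The upstream-lobe area is
    the medium volume (2D area) behind the tip plane outside the catheter;
    a pattern with lobes above ``lobe_threshold_mm2`` is classed as an
    incomplete ellipse, otherwise as a sector.
    """
    a = np.where(field.is_fluid, field.alpha, np.nan)
    contours_idx = measure.find_contours(a, level)
    xc_mm = mesh.xc / MM
    yc_mm = mesh.yc / MM
    polylines = [_index_to_mm(c, yc_mm, xc_mm) for c in contours_idx]

    # pattern area: closed contour loops by the shoelace formula; open
    # polylines (the interface usually meets the catheter wall) fall back
    # to the area of cells where the medium dominates
    cell_mm2 = mesh.cell_area / MM**2
    closed = [c_mm for c_idx, c_mm in zip(contours_idx, polylines)
              if len(c_mm) >= 3 and np.allclose(c_idx[0], c_idx[-1])]
    if closed:
        area = float(sum(Polygon(c).area for c in closed))
    else:
        area = float(cell_mm2[field.is_fluid & (field.alpha >= level)].sum())
    behind = (mesh.xc / MM < tip_x_mm)[None, :] & (mesh.yc / MM > r_oc_mm)[:, None]
    up = float((np.where(field.is_fluid & behind, field.alpha, 0.0)
                * cell_mm2)[behind].sum())
    if not polylines:
        shape = "other"
    else:
        shape = "incomplete_ellipse" if up > lobe_threshold_mm2 else "sector"
    return DispersionPattern(t=field.t, contours=polylines,
                             enclosed_area=area, upstream_area=up,
                             shape_class=shape)


def classify_region(position_x_mm: float, tip_x_mm: float) -> str:
    """Downstream iff strictly fundus-side of the tip; the tip plane itself
    counts as upstream (tie-break convention)."""
    return "downstream" if position_x_mm > tip_x_mm else "upstream"


@dataclass
class TransportSummary:
    """Table-style per-case summary of the ten embryo deliveries."""

    case_index: int | None
    axial_mm: np.ndarray          # per embryo, + toward the fundus
    radial_mm: np.ndarray
    regions: list
    mean_axial_mm: float
    mean_radial_mm: float
    n_upstream: int
    n_downstream: int
    driving_force_N: float | None = None
    dragback_mm: float | None = None
    n_exited_cervix: int = 0      # left the domain through the external os
    n_entered_cervix: int = 0     # ended cervix-side of the internal os


def transport_distances(trajectories, tip_x_mm: float, t_ref: float,
                        case_index: int | None = None) -> TransportSummary:
    """Axial / radial transport distances relative to the tip at ``t_ref``.

    Embryos that exited before ``t_ref`` enter with their exit position and
    are flagged through their recorded status.
    """
    ax, rad, regions = [], [], []
    for tr in trajectories:
        s = tr.at(t_ref)
        x_mm, y_mm = s.x / MM, s.y / MM
        ax.append(x_mm - tip_x_mm)
        rad.append(abs(y_mm))
        regions.append(s.status if s.frozen else classify_region(x_mm, tip_x_mm))
    ax = np.asarray(ax)
    rad = np.asarray(rad)
    return TransportSummary(
        case_index=case_index,
        axial_mm=ax, radial_mm=rad, regions=regions,
        mean_axial_mm=float(ax.mean()), mean_radial_mm=float(rad.mean()),
        n_upstream=sum(r == "upstream" for r in regions),
        n_downstream=sum(r == "downstream" for r in regions),
    )


def withdrawal_dragback(trajectories, t_end_injection: float,
                        t_end_withdrawal: float) -> tuple[float, int]:
    """Mean axial displacement toward the cervix over the withdrawal,
    ``x(t_inj) - x(t_end)`` averaged over embryos (positive = toward the
    cervix), plus the number of embryos that left through the cervix."""
    if t_end_withdrawal <= t_end_injection:
        return 0.0, 0
    back = []
    exited = 0
    for tr in trajectories:
        s0 = tr.at(t_end_injection)
        s1 = tr.at(t_end_withdrawal)
        back.append((s0.x - s1.x) / MM)
        exited += s1.status == "exited_cervix"
    return float(np.mean(back)), exited


def driving_force(inlet_pressure_Pa: float, r_c_mm: float) -> float:
    """Injection driving force (N): mean inlet gauge pressure times the
    circular bore area pi r_c^2."""
    return inlet_pressure_Pa * np.pi * (r_c_mm * MM) ** 2


def force_per_depth(inlet_pressure_Pa: float, r_c_mm: float) -> float:
    """Planar 2D alternative: force per metre of depth (N/m)."""
    return inlet_pressure_Pa * r_c_mm * MM


def trajectories_frame(trajectories) -> pd.DataFrame:
    """Long-form CSV-ready table (t, id, x, y, vx, vy, status), mm units."""
    rows = []
    for tr in trajectories:
        for t, s in zip(tr.times, tr.states):
            rows.append((t, s.id, s.x / MM, s.y / MM,
                         s.vx / MM, s.vy / MM, s.status))
    return pd.DataFrame(rows, columns=["t", "id", "x_mm", "y_mm",
                                       "vx_mm_s", "vy_mm_s", "status"])


def summary_frame(summaries, viscosities=None, speeds=None) -> pd.DataFrame:
    """Table-2-shaped frame across cases."""
    rows = []
    for k, s in enumerate(summaries):
        rows.append(dict(
            case=s.case_index,
            mu1_Pa_s=None if viscosities is None else viscosities[k],
            injection_speed_mm_s=None if speeds is None else speeds[k],
            mean_axial_mm=s.mean_axial_mm,
            mean_radial_mm=s.mean_radial_mm,
            n_upstream=s.n_upstream,
            n_downstream=s.n_downstream,
            driving_force_mN=None if s.driving_force_N is None
            else s.driving_force_N * 1e3,
            dragback_mm=s.dragback_mm,
            n_exited_cervix=s.n_exited_cervix,
            n_entered_cervix=s.n_entered_cervix,
        ))
    return pd.DataFrame(rows)
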