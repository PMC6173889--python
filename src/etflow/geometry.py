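"""Half-symmetric uterine-cavity geometry and finite-volume meshing.

The computational domain is the mid-sagittal half cross-section of the
uterus: a straight cervical channel joined to a triangular cavity, with a
transcervical catheter lying along the symmetry midline.  Coordinates are
axial ``x`` (increasing from the external ostium toward the fundus) and
radial ``y`` (``y = 0`` on the midline).  Geometry parameters are given in
millimetres; meshes store coordinates in metres (SI) for the flow solver.

The mesh is a tensor-product Cartesian grid with solid-cell blanking: the
triangular lateral wall is stair-stepped, and the catheter is a
time-dependent solid mask so that withdrawal is a moving mask rather than a
moving mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely.geometry import Point, Polygon

MM = 1e-3  # metres per millimetre

# boundary-condition kinds used by the flow solver
KIND_WALL = 0      # no-slip wall; may move (tangential and/or normal velocity)
KIND_SYMMETRY = 1  # midline: zero normal velocity, zero normal gradients
KIND_PRESSURE = 2  # fixed gauge pressure, zero-gradient velocity / alpha
KIND_FLUX = 3      # prescribed volume flux carrying a given velocity / alpha


class GeometryError(ValueError):
    """Inconsistent geometric parameters."""


@dataclass(frozen=True)
class UterusGeometry:
    """Dimensions of the half uterine cavity, cervix and catheter (mm)."""

    cavity_base: float = 32.0
    cavity_height: float = 50.0
    cervix_length: float = 25.0
    external_ostium_width: float = 4.0
    tube_ostium_width: float = 0.3
    catheter_inner_diameter: float = 0.6
    catheter_outer_diameter: float = 0.8
    catheter_length_in_cavity: float = 56.0
    tip_fundus_distance: float = 15.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        if self.catheter_outer_diameter <= self.catheter_inner_diameter:
            raise GeometryError("catheter outer diameter must exceed inner diameter")
        if self.tip_fundus_distance >= self.cavity_height:
            raise GeometryError(
                "catheter tip would lie at or behind the cavity apex "
                f"(tip_fundus_distance={self.tip_fundus_distance} mm, "
                f"cavity_height={self.cavity_height} mm)"
            )
        if self.tip_x - self.catheter_length_in_cavity < 0:
            raise GeometryError("catheter entry would lie outside the domain")

    # -- derived axial landmarks (mm) --
    @property
    def apex_x(self) -> float:
        return self.cervix_length

    @property
    def fundus_x(self) -> float:
        return self.cervix_length + self.cavity_height

    @property
    def tip_x(self) -> float:
        """Axial position of the catheter tip before withdrawal."""
        return self.fundus_x - self.tip_fundus_distance

    @property
    def entry_x(self) -> float:
        """Axial position of the catheter bore entrance (plunger at rest)."""
        return self.tip_x - self.catheter_length_in_cavity

    @property
    def r_c(self) -> float:
        """Inner (bore) radius, mm."""
        return self.catheter_inner_diameter / 2.0

    @property
    def r_oc(self) -> float:
        """Outer radius, mm."""
        return self.catheter_outer_diameter / 2.0

    @property
    def half_base(self) -> float:
        return self.cavity_base / 2.0

    @property
    def half_cervix(self) -> float:
        return self.external_ostium_width / 2.0


@dataclass(frozen=True)
class DomainOutline:
    """Continuous description of the half domain (all lengths mm)."""

    params: UterusGeometry
    polygon: Polygon                      # fluid half-domain outline
    catheter_wall: tuple[float, float, float, float]  # (x0, x1, y0, y1) wall band
    tube_ostium: tuple[float, float]      # y-interval on the fundus boundary
    external_ostium: tuple[float, float]  # y-interval on the x = 0 boundary
    tip_x: float
    entry_x: float

    @property
    def area(self) -> float:
        """Continuum fluid area of the half domain (mm^2), catheter excluded."""
        x0, x1, y0, y1 = self.catheter_wall
        return self.polygon.area - (x1 - x0) * (y1 - y0)


def build_geometry(params: UterusGeometry | None = None) -> DomainOutline:
    """Assemble the continuous half-domain outline from the dimensions.

    The fluid region is the union of the cervical channel (uniform half
    width) and the triangular half cavity; the channel wall is extended to
    where the sloped cavity wall reaches the channel half width, so the
    cervix–cavity junction stays open.  The catheter wall occupies the band
    ``r_c <= y <= r_oc`` between the bore entrance and the tip.
    """
    g = params or UterusGeometry()
    slope = g.half_base / g.cavity_height
    x_join = g.apex_x + g.half_cervix / slope
    poly = Polygon(
        [
            (0.0, 0.0),
            (g.fundus_x, 0.0),
            (g.fundus_x, g.half_base),
            (x_join, g.half_cervix),
            (0.0, g.half_cervix),
        ]
    )
    return DomainOutline(
        params=g,
        polygon=poly,
        catheter_wall=(g.entry_x, g.tip_x, g.r_c, g.r_oc),
        tube_ostium=(g.half_base - g.tube_ostium_width, g.half_base),
        external_ostium=(0.0, g.half_cervix),
        tip_x=g.tip_x,
        entry_x=g.entry_x,
    )


# ---------------------------------------------------------------------------
# withdrawal kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WithdrawalProtocol:
    """Constant-speed catheter withdrawal starting at the end of injection.

    The withdrawal distance is chosen so the tip clears the external ostium
    within the fixed 5 s duration; it is a configuration knob.
    """

    enabled: bool = True
    start_time: float = 1.0       # s, = end of injection
    duration: float = 5.0         # s
    distance: float = 81.0        # mm

    @property
    def speed(self) -> float:
        """Withdrawal speed, mm/s."""
        return self.distance / self.duration


def catheter_position(t: float, protocol: WithdrawalProtocol) -> tuple[float, float]:
    """Axial catheter offset (mm, toward the cervix) and wall speed (mm/s).

    Before withdrawal both are zero; during withdrawal the catheter
    translates toward the cervix at constant speed, and the moving-wall
    speed applies on the tip, inner and outer catheter walls.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if not protocol.enabled or t <= protocol.start_time:
        return 0.0, 0.0
    if t >= protocol.start_time + protocol.duration:
        return protocol.distance, 0.0
    return protocol.speed * (t - protocol.start_time), protocol.speed


# ---------------------------------------------------------------------------
# tensor-product mesh with blanking
# ---------------------------------------------------------------------------

def _graded(x0: float, x1: float, d0: float, dmax: float, ratio: float) -> np.ndarray:
    """Face coordinates from x0 to x1, spacing growing geometrically from d0
    capped at dmax, rescaled so the last face lands exactly on x1."""
    ds = []
    d = d0
    total = 0.0
    span = x1 - x0
    while total < span:
        ds.append(d)
        total += d
        d = min(d * ratio, dmax)
    ds = np.asarray(ds)
    ds *= span / ds.sum()
    return x0 + np.concatenate(([0.0], np.cumsum(ds)))


def _uniform(x0: float, x1: float, d: float) -> np.ndarray:
    n = max(1, round((x1 - x0) / d))
    return np.linspace(x0, x1, n + 1)


def _merge_faces(faces: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Sorted unique face coordinates, collapsing near-duplicates that would
    otherwise create degenerate cells."""
    f = np.sort(np.asarray(faces, float))
    keep = np.concatenate(([True], np.diff(f) > tol))
    return f[keep]


@dataclass
class FaceSet:
    """Flattened face connectivity for one catheter position / flow regime.

    Internal faces connect two fluid cells; boundary faces carry a BC
    descriptor.  Signed fluxes through faces follow the +x / +y convention;
    the outward flux for the adjacent cell of a boundary face is
    ``side * Q``.
    """

    n: int
    is_fluid: np.ndarray      # (Ny, Nx) bool
    idx: np.ndarray           # (Ny, Nx) int, -1 outside fluid
    # internal faces
    int_P: np.ndarray
    int_N: np.ndarray
    int_A: np.ndarray
    int_delta: np.ndarray
    int_w: np.ndarray         # interpolation weight of P at the face
    int_dir: np.ndarray       # 0 = x-normal, 1 = y-normal
    # boundary faces
    b_cell: np.ndarray
    b_A: np.ndarray
    b_dh: np.ndarray          # cell-centre to face distance
    b_dir: np.ndarray
    b_side: np.ndarray        # +1: face on the +x/+y side of the cell
    b_kind: np.ndarray
    b_uw: np.ndarray          # wall / carried x-velocity
    b_vw: np.ndarray
    b_p0: np.ndarray
    b_alpha: np.ndarray       # inflow alpha; NaN = zero-gradient
    b_Q: np.ndarray           # prescribed signed flux (wall / flux kinds)
    b_label: np.ndarray       # tag names: INLET, WALL, SYMMETRY, OUTFLOW_*


class TensorMesh:
    """Cartesian tensor-product mesh (SI metres) over a blanked domain."""

    def __init__(self, xf: np.ndarray, yf: np.ndarray, base_fluid: np.ndarray):
        self.xf = np.asarray(xf, float)
        self.yf = np.asarray(yf, float)
        self.xc = 0.5 * (self.xf[:-1] + self.xf[1:])
        self.yc = 0.5 * (self.yf[:-1] + self.yf[1:])
        self.dx = np.diff(self.xf)
        self.dy = np.diff(self.yf)
        self.nx = self.xc.size
        self.ny = self.yc.size
        if base_fluid.shape != (self.ny, self.nx):
            raise ValueError("base_fluid shape does not match grid")
        self.base_fluid = base_fluid.astype(bool)
        self.cell_area = np.outer(self.dy, self.dx)  # (Ny, Nx), m^2 per metre depth

    @property
    def h(self) -> float:
        """Characteristic resolution (m): largest cell extent."""
        return max(self.dx.max(), self.dy.max())

    def fluid_area(self, is_fluid: np.ndarray | None = None) -> float:
        mask = self.base_fluid if is_fluid is None else is_fluid
        return float(self.cell_area[mask].sum())

    # -- face enumeration ---------------------------------------------------
    def _enumerate(self, is_fluid: np.ndarray, severed_x: np.ndarray | None):
        """Raw face lists.  ``severed_x`` is a (Ny, Nx+1) bool marking x-face
        planes that must be split into two one-sided boundary faces (the
        catheter plunger / inlet plane)."""
        ny, nx = is_fluid.shape
        idx = np.full((ny, nx), -1, dtype=np.int64)
        n = int(is_fluid.sum())
        idx[is_fluid] = np.arange(n)

        sev = severed_x if severed_x is not None else np.zeros((ny, nx + 1), bool)

        # internal x-faces between (j,i) and (j,i+1)
        both_x = is_fluid[:, :-1] & is_fluid[:, 1:] & ~sev[:, 1:-1]
        jx, ix = np.nonzero(both_x)
        # internal y-faces between (j,i) and (j+1,i)
        both_y = is_fluid[:-1, :] & is_fluid[1:, :]
        jy, iy = np.nonzero(both_y)

        internal = dict(
            P=np.concatenate([idx[jx, ix], idx[jy, iy]]),
            N=np.concatenate([idx[jx, ix + 1], idx[jy + 1, iy]]),
            A=np.concatenate([self.dy[jx], self.dx[iy]]),
            delta=np.concatenate(
                [self.xc[ix + 1] - self.xc[ix], self.yc[jy + 1] - self.yc[jy]]
            ),
            w=np.concatenate(
                [
                    (self.xc[ix + 1] - self.xf[ix + 1]) / (self.xc[ix + 1] - self.xc[ix]),
                    (self.yc[jy + 1] - self.yf[jy + 1]) / (self.yc[jy + 1] - self.yc[jy]),
                ]
            ),
            dir=np.concatenate([np.zeros(jx.size, np.int8), np.ones(jy.size, np.int8)]),
        )

        # boundary faces: a fluid cell face whose far side is not a fluid cell
        # (domain edge, blanked cell) or a severed plane.
        fl = is_fluid
        pad_x = np.zeros((ny, nx + 2), bool)
        pad_x[:, 1:-1] = fl
        pad_y = np.zeros((ny + 2, nx), bool)
        pad_y[1:-1, :] = fl

        records: list[tuple] = []  # (cell_j, cell_i, face_index, dir, side)
        # west faces
        jj, ii = np.nonzero(fl & (~pad_x[:, :-2] | sev[:, :-1]))
        records.append((jj, ii, ii, 0, -1))
        # east faces
        jj, ii = np.nonzero(fl & (~pad_x[:, 2:] | sev[:, 1:]))
        records.append((jj, ii, ii + 1, 0, +1))
        # south faces
        jj, ii = np.nonzero(fl & ~pad_y[:-2, :])
        records.append((jj, ii, jj, 1, -1))
        # north faces
        jj, ii = np.nonzero(fl & ~pad_y[2:, :])
        records.append((jj, ii, jj + 1, 1, +1))

        bj = np.concatenate([r[0] for r in records])
        bi = np.concatenate([r[1] for r in records])
        bf = np.concatenate([np.asarray(r[2]) for r in records])
        bdir = np.concatenate([np.full(r[0].size, r[3], np.int8) for r in records])
        bside = np.concatenate([np.full(r[0].size, r[4], np.int8) for r in records])

        isx = bdir == 0
        bA = np.where(isx, self.dy[bj], self.dx[bi])
        face_coord = np.empty(bf.size)
        face_coord[isx] = self.xf[bf[isx]]
        face_coord[~isx] = self.yf[bf[~isx]]
        centre = np.where(isx, self.xc[bi], self.yc[bj])
        bdh = np.abs(face_coord - centre)

        boundary = dict(j=bj, i=bi, f=bf, dir=bdir, side=bside, A=bA, dh=bdh)
        return n, idx, internal, boundary

    def build_faces(
        self,
        is_fluid: np.ndarray,
        tagger: Callable,
        severed_x: np.ndarray | None = None,
    ) -> FaceSet:
        """Enumerate faces and apply ``tagger`` to the boundary faces.

        ``tagger(j, i, f, dir, side)`` receives index arrays and returns the
        per-face arrays ``kind, uw, vw, p0, alpha_in, label`` (velocities in
        m/s; the prescribed signed flux is derived from the normal velocity
        component).
        """
        n, idx, internal, boundary = self._enumerate(is_fluid, severed_x)
        kind, uw, vw, p0, alpha_in, label = tagger(
            boundary["j"], boundary["i"], boundary["f"], boundary["dir"], boundary["side"]
        )
        vn = np.where(boundary["dir"] == 0, uw, vw)  # face-normal wall velocity
        bQ = np.where(kind == KIND_FLUX, vn * boundary["A"], 0.0)
        bQ = np.where(kind == KIND_WALL, vn * boundary["A"], bQ)
        return FaceSet(
            n=n,
            is_fluid=is_fluid,
            idx=idx,
            int_P=internal["P"],
            int_N=internal["N"],
            int_A=internal["A"],
            int_delta=internal["delta"],
            int_w=internal["w"],
            int_dir=internal["dir"],
            b_cell=idx[boundary["j"], boundary["i"]],
            b_A=boundary["A"],
            b_dh=boundary["dh"],
            b_dir=boundary["dir"],
            b_side=boundary["side"],
            b_kind=kind.astype(np.int8),
            b_uw=uw,
            b_vw=vw,
            b_p0=p0,
            b_alpha=alpha_in,
            b_Q=bQ,
            b_label=label,
        )


def box_mesh(
    lx: float,
    ly: float,
    nx: int,
    ny: int,
    tags: dict[str, tuple],
) -> tuple[TensorMesh, FaceSet]:
    """Uniform rectangular mesh with per-side boundary conditions.

    ``tags`` maps sides ``W/E/S/N`` to descriptors:
    ``("wall", uw, vw)``, ``("symmetry",)``, ``("pressure", p0)`` or
    ``("flux", u, v, alpha)``.  A side descriptor may also be a callable
    ``f(coords) -> tuple`` evaluated with the face-centre coordinate along
    the side, to model e.g. an inlet slot in a wall.  Used for solver
    verification cases (channel flows, jets).
    """
    xf = np.linspace(0.0, lx, nx + 1)
    yf = np.linspace(0.0, ly, ny + 1)
    mesh = TensorMesh(xf, yf, np.ones((ny, nx), bool))

    kinds = {"wall": KIND_WALL, "symmetry": KIND_SYMMETRY,
             "pressure": KIND_PRESSURE, "flux": KIND_FLUX}

    def unpack(desc):
        name = desc[0]
        k = kinds[name]
        uw = vw = p0 = 0.0
        a = np.nan
        if name == "wall":
            uw, vw = desc[1], desc[2]
        elif name == "pressure":
            p0 = desc[1]
        elif name == "flux":
            uw, vw, a = desc[1], desc[2], desc[3]
        return k, uw, vw, p0, a

    def tagger(j, i, f, bdir, side):
        m = j.size
        kind = np.zeros(m, np.int8)
        uw = np.zeros(m)
        vw = np.zeros(m)
        p0 = np.zeros(m)
        alpha = np.full(m, np.nan)
        label = np.empty(m, object)
        sides = np.where(
            bdir == 0, np.where(side < 0, "W", "E"), np.where(side < 0, "S", "N")
        )
        coord = np.where(bdir == 0, mesh.yc[j], mesh.xc[i])
        for name in ("W", "E", "S", "N"):
            sel = sides == name
            if not sel.any():
                continue
            desc = tags[name]
            if callable(desc):
                for p in np.nonzero(sel)[0]:
                    k, u_, v_, pp, a_ = unpack(desc(coord[p]))
                    kind[p], uw[p], vw[p], p0[p], alpha[p] = k, u_, v_, pp, a_
            else:
                k, u_, v_, pp, a_ = unpack(desc)
                kind[sel], uw[sel], vw[sel], p0[sel], alpha[sel] = k, u_, v_, pp, a_
            label[sel] = name
        return kind, uw, vw, p0, alpha, label

    return mesh, mesh.build_faces(mesh.base_fluid, tagger)


# ---------------------------------------------------------------------------
# uterus mesh
# ---------------------------------------------------------------------------

class UterusMesh(TensorMesh):
    """Blanked Cartesian mesh of the half uterine cavity with the catheter.

    The grid is graded: 0.1 mm cells across the catheter bore and wall near
    the midline (at least three cells across the half bore), refinement in x
    near the catheter tip, and geometric coarsening toward the lateral wall.
    The top row is sized to the fallopian-tube ostium so the opening is one
    face.  ``face_set`` re-tags boundary faces for a given catheter offset
    and flow regime, which makes withdrawal a time-dependent mask.
    """

    def __init__(
        self,
        outline: DomainOutline,
        h: float = 1.0,
        fine: float = 0.1,
        tip_refine: float = 0.5,
    ):
        if h <= 0 or fine <= 0:
            raise GeometryError("mesh spacings must be positive")
        g = outline.params
        if g.r_c / fine < 3 - 1e-9:
            raise GeometryError(
                f"fine spacing {fine} mm resolves fewer than 3 cells across "
                f"the half bore (r_c = {g.r_c} mm)"
            )
        self.outline = outline
        self.g = g

        # x faces (mm): anchor the bore entrance, tip and fundus
        tip_lo, tip_hi = max(g.entry_x, g.tip_x - 5.0), min(g.fundus_x, g.tip_x + 5.0)
        xs = [
            _uniform(0.0, g.entry_x, h),
            _uniform(g.entry_x, tip_lo, h),
            _uniform(tip_lo, tip_hi, min(tip_refine, h)),
            _uniform(tip_hi, g.fundus_x, h),
        ]
        xf = _merge_faces(np.concatenate(xs))

        # y faces (mm): fine band over bore + wall, graded to the channel
        # half-width, graded again to the ostium row at the lateral corner
        y_fine_top = g.r_oc + 2 * fine
        ys = [
            _uniform(0.0, y_fine_top, fine),
            _graded(y_fine_top, g.half_cervix, fine * 1.2, h, 1.3),
            _graded(g.half_cervix, g.half_base - g.tube_ostium_width, 0.4 * h, 2.5 * h, 1.3),
            np.array([g.half_base - g.tube_ostium_width, g.half_base]),
        ]
        yf = _merge_faces(np.concatenate(ys))

        xc = 0.5 * (xf[:-1] + xf[1:])
        yc = 0.5 * (yf[:-1] + yf[1:])
        inside = np.zeros((yc.size, xc.size), bool)
        poly = outline.polygon
        for jj, y in enumerate(yc):
            for ii, x in enumerate(xc):
                inside[jj, ii] = poly.contains(Point(x, y))
        # keep the fallopian-tube ostium open: the triangle corner cells in
        # the ostium row count as fluid if they overlap the cavity at the
        # row's bottom edge (centre-based blanking would seal the corner)
        slope = g.half_base / g.cavity_height
        j_top = yc > (g.half_base - g.tube_ostium_width)
        x_wall = g.apex_x + (g.half_base - g.tube_ostium_width) / slope
        inside[np.ix_(j_top, xf[1:] > x_wall)] = True
        super().__init__(xf * MM, yf * MM, inside)
        self.xc_mm = xc
        self.yc_mm = yc
        self.xf_mm = xf
        self.yf_mm = yf
        # row bands (by cell centre)
        self.rows_bore = yc < g.r_c
        self.rows_wall = (yc > g.r_c) & (yc < g.r_oc)
        self.rows_ostium = yc > (g.half_base - g.tube_ostium_width)

    # -- catheter blanking --------------------------------------------------
    def catheter_mask(self, offset_mm: float) -> np.ndarray:
        """Solid cells of the catheter wall band at a given axial offset."""
        g = self.g
        x0, x1 = g.entry_x - offset_mm, g.tip_x - offset_mm
        cols = (self.xc_mm > x0) & (self.xc_mm < x1)
        return self.base_fluid & np.outer(self.rows_wall, cols)

    def bore_mask(self, offset_mm: float = 0.0) -> np.ndarray:
        """Fluid cells inside the catheter bore at a given offset."""
        g = self.g
        cols = (self.xc_mm > g.entry_x - offset_mm) & (self.xc_mm < g.tip_x - offset_mm)
        return self.base_fluid & np.outer(self.rows_bore, cols)

    def mask_key(self, offset_mm: float, regime: str) -> tuple:
        """Hashable key identifying the discrete mask/BC state."""
        cath = self.catheter_mask(offset_mm)
        cols = np.nonzero(cath.any(axis=0))[0]
        i0 = int(cols[0]) if cols.size else -1
        i1 = int(cols[-1]) if cols.size else -1
        return (regime, i0, i1, self._plunger_face(offset_mm))

    def _plunger_face(self, offset_mm: float) -> int:
        """Index of the x-face plane nearest the bore entrance, or -1 if the
        plunger has left the domain."""
        xb = self.g.entry_x - offset_mm
        if xb <= self.xf_mm[0]:
            return -1
        return int(np.argmin(np.abs(self.xf_mm - xb)))

    # -- boundary tagging ---------------------------------------------------
    def face_set(
        self,
        offset_mm: float,
        wall_speed_mm_s: float,
        inlet_speed_m_s: float,
    ) -> FaceSet:
        """Faces + BCs for one catheter position.

        ``inlet_speed_m_s > 0`` marks the injection regime (plug inflow of
        transferred medium at the bore entrance); ``wall_speed_mm_s > 0``
        marks withdrawal (moving catheter walls, plunger following).  With
        both zero the bore entrance is a closed, resting plunger.
        """
        g = self.g
        cath = self.catheter_mask(offset_mm)
        is_fluid = self.base_fluid & ~cath
        uw_cath = -wall_speed_mm_s * MM  # catheter wall velocity, m/s (toward cervix)

        ip = self._plunger_face(offset_mm)
        severed = np.zeros((self.ny, self.nx + 1), bool)
        if ip >= 1 and ip <= self.nx - 1:
            severed[self.rows_bore, ip] = True

        half_cervix_m = g.half_cervix * MM
        catheter_at_west = (g.entry_x - offset_mm) < 0.0 < (g.tip_x - offset_mm)

        cath_pad = np.zeros((self.ny + 2, self.nx + 2), bool)
        cath_pad[1:-1, 1:-1] = cath

        def tagger(j, i, f, bdir, side):
            m = j.size
            kind = np.zeros(m, np.int8)
            uw = np.zeros(m)
            vw = np.zeros(m)
            p0 = np.zeros(m)
            alpha = np.full(m, np.nan)
            label = np.full(m, "WALL", object)

            # neighbour cell across the face is a catheter solid cell?
            nj = j + np.where(bdir == 1, side, 0)
            ni = i + np.where(bdir == 0, side, 0)
            near_cath = cath_pad[nj + 1, ni + 1]
            uw[near_cath] = uw_cath

            xface = bdir == 0
            # severed plunger plane
            at_plunger = xface & (f == ip) & (ip >= 0)
            bore_side = at_plunger & (side < 0)
            cerv_side = at_plunger & (side > 0)
            if inlet_speed_m_s > 0.0:
                kind[bore_side] = KIND_FLUX
                uw[bore_side] = inlet_speed_m_s
                alpha[bore_side] = 1.0
                label[bore_side] = "INLET"
                # cervix side: resting catheter butt (wall, defaults)
            else:
                # closed plunger; moves with the catheter during withdrawal
                uw[bore_side] = uw_cath
                kind[bore_side] = KIND_FLUX  # one-sided moving face, no viscous link
                uw[cerv_side] = uw_cath

            # west domain edge (x = 0)
            west = xface & (f == 0)
            if catheter_at_west:
                w_wall = west & (self.rows_wall[j] | self.rows_bore[j])
                uw[w_wall] = uw_cath
                kind[w_wall & self.rows_bore[j]] = KIND_FLUX
                w_open = west & (self.yc[j] > g.r_oc * MM) & (self.yc[j] < half_cervix_m)
                kind[w_open] = KIND_PRESSURE
                label[w_open] = "OUTFLOW_EXT"
            else:
                w_open = west & (self.yc[j] < half_cervix_m)
                kind[w_open] = KIND_PRESSURE
                label[w_open] = "OUTFLOW_EXT"

            # fundus edge: fallopian-tube ostium on the top rows
            east_end = xface & (f == self.nx) & (side > 0)
            tube = east_end & self.rows_ostium[j]
            kind[tube] = KIND_PRESSURE
            label[tube] = "OUTFLOW_TUBE"

            # midline symmetry
            south = (bdir == 1) & (f == 0) & (side < 0)
            kind[south] = KIND_SYMMETRY
            uw[south] = 0.0
            label[south] = "SYMMETRY"

            label[(kind == KIND_WALL) & near_cath] = "WALL"
            return kind, uw, vw, p0, alpha, label

        return self.build_faces(is_fluid, tagger, severed)


def build_mesh(
    outline: DomainOutline,
    h: float = 1.0,
    fine: float = 0.1,
    tip_refine: float = 0.5,
) -> UterusMesh:
    """Discretise the half domain; ``h`` is the coarse spacing (mm)."""
    return UterusMesh(outline, h=h, fine=fine, tip_refine=tip_refine)
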