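"""Parametric 2D end-to-side anastomosis geometry with graded stenosis.

Generates idealized planar (symmetry-plane) geometries of a graft joined to
a host coronary artery over a 10 mm arteriotomy, as wall polylines plus a
rasterized fluid mask on a uniform Cartesian grid.  Three stenosis
mechanisms are modelled:

* longitudinal shortening — heel and toe move symmetrically toward the
  orifice centre, shortening the orifice to (1 - grade) of the arteriotomy
  and steepening the effective inflow angle;
* bilateral narrowing — a smooth symmetric constriction at the graft-host
  junction reduces the open passage to (1 - grade) of the graft width
  (planar surrogate for suture narrowing of the sides);
* native coronary stenosis — a smooth symmetric narrowing of the proximal
  host channel to (1 - native_grade) of its diameter; 100% is built as a
  sealed wall truncating the proximal segment.

Coordinate convention: x along the host axis (flow left to right), y
transverse, host floor on y = 0.  All lengths in mm; the solver converts
to SI.  Stenosis grades are fractional reductions of a linear dimension
(orifice length / passage width / diameter).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "PATTERNS",
    "GRADES",
    "NATIVE_GRADES",
    "StenosisSpec",
    "GeometryParams",
    "AnastomosisGeometry",
    "GeometryResolutionError",
    "ResolutionWarning",
    "enumerate_study_matrix",
    "make_geometry",
    "make_channel_geometry",
    "make_box_geometry",
    "geometry_report",
]

PATTERNS = ("none", "longitudinal", "bilateral")
GRADES = (0.0, 0.25, 0.50, 0.75)
NATIVE_GRADES = (0.90, 1.00)

_PATTERN_SHORT = {"none": "ref", "longitudinal": "long", "bilateral": "bila"}


class GeometryResolutionError(ValueError):
    """Narrowest anastomotic passage too coarse for the requested grid."""


class ResolutionWarning(UserWarning):
    """Anastomotic passage resolved by fewer than 8 cells."""


@dataclass(frozen=True)
class StenosisSpec:
    """One of the 14 study configurations.

    ``pattern`` is the anastomotic stenosis mechanism, ``grade`` its severity
    as a linear-dimension fraction, and ``native_grade`` the diameter
    reduction of the proximal native coronary artery.
    """

    pattern: str = "none"
    grade: float = 0.0
    native_grade: float = 0.90

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.grade not in GRADES:
            raise ValueError(f"grade {self.grade} not in allowed set {GRADES}")
        if self.native_grade not in NATIVE_GRADES:
            raise ValueError(
                f"native_grade {self.native_grade} not in allowed set {NATIVE_GRADES}"
            )
        if (self.pattern == "none") != (self.grade == 0.0):
            raise ValueError("pattern 'none' if and only if grade == 0")

    @property
    def model_id(self) -> str:
        return (
            f"{_PATTERN_SHORT[self.pattern]}{int(round(self.grade * 100)):02d}"
            f"_n{int(round(self.native_grade * 100)):03d}"
        )


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the idealized anastomosis (mm, degrees).

    Host diameters and arteriotomy length follow the modelled surgical
    construction (2.8 mm proximal, 3.2 mm distal, 10 mm arteriotomy); the
    host channel tapers linearly between heel and toe of the reference
    anastomosis.
    Graft diameter and take-off angle are configurable (3.0 mm / 30 deg
    defaults).
    """

    host_diam_proximal: float = 2.8
    host_diam_distal: float = 3.2
    arteriotomy_length: float = 10.0
    graft_diam: float = 3.0
    graft_angle: float = 30.0
    host_length_proximal: float = 10.0
    host_length_distal: float = 10.0
    native_stenosis_length: float = 2.0
    native_stenosis_offset: float = 7.5   # throat centre, mm proximal of reference heel
    junction_length: float = 4.0          # funnel length along the graft centreline
    domain_top: float = 8.0               # y of the graft inlet cut
    bottom_margin: float = 0.3            # solid margin below the floor

    def __post_init__(self):
        for name in (
            "host_diam_proximal", "host_diam_distal", "arteriotomy_length",
            "graft_diam", "host_length_proximal", "host_length_distal",
            "native_stenosis_length", "junction_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.graft_angle < 90.0):
            raise ValueError("graft_angle must lie strictly between 0 and 90 degrees")


@dataclass
class AnastomosisGeometry:
    """Wall polylines + rasterized fluid mask of one model.

    ``wall_polylines`` maps wall names to (N, 2) mm point arrays; each wall
    carries an arclength parametrization starting at its first point.
    ``fluid_mask[j, i]`` is True where the cell centre at
    (origin + (i+1/2)h, origin + (j+1/2)h) lies inside the fluid polygon.
    Open boundaries sit on the bounding-box edges: host inlet (left), host
    outlet (right), graft inlet (top).
    """

    spec: StenosisSpec
    params: GeometryParams
    h: float                              # grid spacing, mm
    origin: tuple                         # (x0, y0) of the grid, mm
    fluid_mask: np.ndarray
    wall_polylines: dict
    landmarks: dict
    polygon: Polygon
    open_boundaries: dict                 # name -> dict(side=..., index=array)
    orifice_length: float
    min_passage: float                    # narrowest anastomotic passage, mm
    native_passage: float                 # native throat opening, mm (0 if sealed)
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.fluid_mask.shape

    def arclength(self, wall: str) -> np.ndarray:
        pts = self.wall_polylines[wall]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def cell_centers(self):
        ny, nx = self.fluid_mask.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.h
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.h
        return x, y


def enumerate_study_matrix() -> list:
    """All 14 model configurations, ordered by (native_grade, pattern, grade)."""
    specs = []
    for native in NATIVE_GRADES:
        for pattern in PATTERNS:
            grades = (0.0,) if pattern == "none" else (0.25, 0.50, 0.75)
            for g in grades:
                specs.append(StenosisSpec(pattern, g, native))
    return specs


def _cos_bump(x, center, half_width, depth):
    """Cosine-tapered bump: ``depth`` at centre, zero outside the window."""
    x = np.asarray(x, dtype=float)
    u = np.clip((x - center) / half_width, -1.0, 1.0)
    return depth * 0.5 * (1.0 + np.cos(np.pi * u)) * (np.abs((x - center) / half_width) < 1.0)


def make_geometry(spec: StenosisSpec, params: GeometryParams | None = None,
                  h: float = 0.1) -> AnastomosisGeometry:
    """Build one anastomosis geometry at grid spacing ``h`` (mm)."""
    if params is None:
        params = GeometryParams()
    if h <= 0:
        raise ValueError("grid spacing must be positive")
    p = params
    Dp, Dd = p.host_diam_proximal, p.host_diam_distal
    La = p.arteriotomy_length
    w = p.graft_diam
    x_heel_ref = p.host_length_proximal
    x_toe_ref = x_heel_ref + La
    Lx = x_toe_ref + p.host_length_distal
    xc = 0.5 * (x_heel_ref + x_toe_ref)

    L_orif = La * (1.0 - spec.grade) if spec.pattern == "longitudinal" else La
    x_heel = xc - 0.5 * L_orif
    x_toe = xc + 0.5 * L_orif

    def roof(x):
        x = np.asarray(x, dtype=float)
        frac = np.clip((x - x_heel_ref) / La, 0.0, 1.0)
        return Dp + (Dd - Dp) * frac

    # Longitudinal shortening rotates the graft axis toward the vertical:
    # the axial footprint of the graft on the host scales with the orifice
    # length, tan(theta_eff) = tan(theta_0) / (1 - grade), so the inflow
    # steepens smoothly as the orifice shortens (30 -> 66.6 deg at 75%).
    theta0 = math.radians(p.graft_angle)
    if spec.pattern == "longitudinal":
        theta = math.atan(math.tan(theta0) / (1.0 - spec.grade))
    else:
        theta = theta0
    d = np.array([-math.cos(theta), math.sin(theta)])   # up the graft
    nvec = np.array([math.sin(theta), math.cos(theta)])  # toward the toe side
    M = np.array([xc, float(roof(xc))])

    def tube_point(s, offset):
        """Point on the graft tube: distance s along centreline, lateral offset."""
        return M + s * d + offset * nvec

    s_j = p.junction_length
    y_top = p.domain_top

    def s_at_top(offset):
        # solve (M + s d + offset n).y == y_top for s
        return (y_top - (M[1] + offset * nvec[1])) / d[1]

    # Bilateral narrowing: cosine bumps on both tube walls near the junction.
    bump_c = s_j + 1.5
    bump_hw = 1.5
    bil_depth = 0.5 * spec.grade * w if spec.pattern == "bilateral" else 0.0

    def tube_wall(offset_sign, s_start, ds):
        """Sampled tube wall polyline from s_start up to the top cut."""
        s_end = s_at_top(offset_sign * w / 2)
        ss = np.arange(s_start, s_end, ds)
        ss = np.append(ss, s_end)
        off = offset_sign * (w / 2) - offset_sign * _cos_bump(ss, bump_c, bump_hw, bil_depth)
        pts = M[None, :] + ss[:, None] * d[None, :] + off[:, None] * nvec[None, :]
        return pts

    ds = max(h / 2.0, 0.02)
    heel = np.array([x_heel, float(roof(x_heel))])
    toe = np.array([x_toe, float(roof(x_toe))])
    near_wall = np.vstack([heel, tube_wall(-1.0, s_j, ds)])
    far_wall = np.vstack([toe, tube_wall(+1.0, s_j, ds)])
    near_top = near_wall[-1]
    far_top = far_wall[-1]

    # Native stenosis throat on the proximal host segment.
    xc_n = x_heel_ref - p.native_stenosis_offset
    sealed = spec.native_grade >= 1.0
    x_left = xc_n if sealed else 0.0
    nat_depth = 0.0 if sealed else 0.5 * spec.native_grade * Dp
    nat_hw = 0.5 * p.native_stenosis_length

    def with_native_bump(xs, base, sign):
        ys = base + sign * _cos_bump(xs, xc_n, nat_hw, nat_depth)
        return np.column_stack([xs, ys])

    def x_samples(x0, x1, extra=()):
        xs = np.arange(x0, x1, ds)
        xs = np.unique(np.concatenate([xs, [x1], list(extra)]))
        return xs

    if sealed:
        floor_xs = x_samples(x_left, Lx)
        floor = np.column_stack([floor_xs, np.zeros_like(floor_xs)])
        roofp_xs = x_samples(x_left, x_heel, extra=(x_heel_ref,))
        roof_prox = np.column_stack([roofp_xs, roof(roofp_xs)])
        seal = np.array([[x_left, Dp], [x_left, 0.0]])
    else:
        floor_xs = x_samples(0.0, Lx)
        floor = with_native_bump(floor_xs, 0.0, +1.0)
        roofp_xs = x_samples(0.0, x_heel, extra=(x_heel_ref,))
        roof_prox = with_native_bump(roofp_xs, roof(roofp_xs), -1.0)
        seal = None
    roofd_xs = x_samples(x_toe, Lx, extra=(x_toe_ref,))
    roof_dist = np.column_stack([roofd_xs, roof(roofd_xs)])

    # Assemble the fluid polygon (counter-clockwise).
    ring = [floor]
    ring.append(np.array([[Lx, Dd]]))
    ring.append(roof_dist[::-1])
    ring.append(far_wall)
    ring.append(near_wall[::-1])
    ring.append(roof_prox[::-1])
    if sealed:
        ring.append(seal)
    pts = np.vstack(ring)
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if not poly.is_valid or poly.is_empty:
        raise ValueError(f"degenerate geometry for {spec.model_id}")

    # Rasterize: cell centres strictly inside the polygon are fluid.  The top
    # edge must land exactly on the graft inlet cut, so the bottom margin is
    # rounded up to keep the grid aligned with the open boundaries.
    nx = int(round(Lx / h))
    if abs(nx * h - Lx) > 1e-9:
        raise ValueError(f"domain length {Lx} mm is not a multiple of h={h} mm")
    ny = int(math.ceil((y_top + p.bottom_margin) / h - 1e-9))
    y0 = y_top - ny * h
    xcent = (np.arange(nx) + 0.5) * h
    ycent = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xcent, ycent)
    fluid = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(ny, nx)

    open_bnd = {}
    left = np.flatnonzero(fluid[:, 0])
    right = np.flatnonzero(fluid[:, -1])
    top = np.flatnonzero(fluid[-1, :])
    if left.size:
        open_bnd["host_inlet"] = {"side": "left", "index": left}
    if right.size:
        open_bnd["host_outlet"] = {"side": "right", "index": right}
    if top.size:
        open_bnd["graft_inlet"] = {"side": "top", "index": top}
    if fluid[0, :].any():
        raise ValueError("fluid reaches the bottom margin; geometry is malformed")

    # Narrowest anastomotic passage: orifice gap + sampled tube cross-sections.
    min_passage = _min_anastomotic_passage(
        poly, M, d, nvec, w, s_j, s_at_top(w / 2), x_heel, x_toe
    )
    native_passage = 0.0 if sealed else Dp * (1.0 - spec.native_grade)

    cells = min_passage / h
    if cells < 6.0:
        raise GeometryResolutionError(
            f"anastomotic passage {min_passage:.3f} mm spans only {cells:.1f} cells "
            f"at h={h} mm (< 6); refine the grid"
        )
    if cells < 8.0:
        warnings.warn(
            f"anastomotic passage {min_passage:.3f} mm spans {cells:.1f} cells "
            f"at h={h} mm (< 8 recommended)",
            ResolutionWarning,
            stacklevel=2,
        )

    walls = {
        "floor": floor,
        "roof_proximal": roof_prox,
        "graft_near": near_wall,
        "graft_far": far_wall,
        "roof_distal": roof_dist,
    }
    if seal is not None:
        walls["seal"] = seal

    landmarks = {
        "heel": heel,
        "toe": toe,
        "floor_center": np.array([xc, 0.0]),
        "graft_inlet": 0.5 * (near_top + far_top),
        "host_inlet": np.array([0.0, Dp / 2]),
        "host_outlet": np.array([Lx, Dd / 2]),
    }

    return AnastomosisGeometry(
        spec=spec,
        params=p,
        h=h,
        origin=(0.0, y0),
        fluid_mask=fluid,
        wall_polylines=walls,
        landmarks=landmarks,
        polygon=poly,
        open_boundaries=open_bnd,
        orifice_length=float(x_toe - x_heel),
        min_passage=float(min_passage),
        native_passage=float(native_passage),
        metadata={
            "x_heel": float(x_heel),
            "x_toe": float(x_toe),
            "x_heel_ref": float(x_heel_ref),
            "x_toe_ref": float(x_toe_ref),
            "xc_native": float(xc_n),
            "Lx": float(Lx),
            "graft_direction": d,
            "graft_angle_eff_deg": math.degrees(theta),
        },
    )


def _min_anastomotic_passage(poly, M, d, nvec, w, s_j, s_top, x_heel, x_toe):
    """Smallest open cross-section of the graft junction and tube (mm).

    The orifice itself is measured as the heel-toe gap; the graft tube
    (including any junction constriction bumps) is probed with cross-sections
    perpendicular to the centreline.  When a probe clips several fluid parts,
    only the part containing the centreline point counts.
    """
    widths = [abs(x_toe - x_heel)]
    s_lo, s_hi = s_j + 0.6, s_top - 0.3
    probe_s = np.linspace(s_lo, s_hi, 40) if s_hi > s_lo else ()
    for s in probe_s:
        c = M + s * d
        seg = LineString([c - 0.75 * w * nvec, c + 0.75 * w * nvec])
        inter = seg.intersection(poly)
        if inter.is_empty:
            continue
        parts = getattr(inter, "geoms", [inter])
        pc = Point(c)
        for part in parts:
            if part.distance(pc) < 1e-9:
                widths.append(part.length)
                break
    return float(min(widths))


def make_channel_geometry(length: float, height: float, h: float,
                          margin: float = 0.3) -> AnastomosisGeometry:
    """Straight grid-aligned channel with open left/right ends (validation).

    Floor at y = 0, roof at y = ``height``; reuses the anastomosis geometry
    container so the solver and wall-shear machinery apply unchanged.
    """
    spec = StenosisSpec("none", 0.0, 0.90)
    poly = Polygon([(0, 0), (length, 0), (length, height), (0, height)])
    margin = math.ceil(margin / h - 1e-9) * h   # keep walls face-aligned
    y0 = -margin
    nx = int(round(length / h))
    ny = int(round((height + 2 * margin) / h))
    xcent = (np.arange(nx) + 0.5) * h
    ycent = y0 + (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(xcent, ycent)
    fluid = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(ny, nx)
    floor = np.array([[0.0, 0.0], [length, 0.0]])
    roofl = np.array([[0.0, height], [length, height]])
    geom = AnastomosisGeometry(
        spec=spec,
        params=GeometryParams(),
        h=h,
        origin=(0.0, y0),
        fluid_mask=fluid,
        wall_polylines={"floor": floor, "roof_distal": roofl},
        landmarks={"host_inlet": np.array([0.0, height / 2]),
                   "host_outlet": np.array([length, height / 2])},
        polygon=poly,
        open_boundaries={
            "host_inlet": {"side": "left", "index": np.flatnonzero(fluid[:, 0])},
            "host_outlet": {"side": "right", "index": np.flatnonzero(fluid[:, -1])},
        },
        orifice_length=0.0,
        min_passage=height,
        native_passage=height,
        metadata={"Lx": length, "channel_height": height},
    )
    return geom


def make_box_geometry(size: float, h: float, margin: float = 0.3) -> AnastomosisGeometry:
    """Closed square box (no open boundaries); used for decay sanity checks."""
    geom = make_channel_geometry(size, size, h, margin=margin)
    fluid = geom.fluid_mask.copy()
    fluid[:, 0] = False
    fluid[:, -1] = False
    geom.fluid_mask = fluid
    geom.open_boundaries = {}
    return geom


def geometry_report(geom: AnastomosisGeometry) -> dict:
    """Morphological metrics of one model (clinical units)."""
    s = geom.spec
    return {
        "model_id": s.model_id,
        "pattern": s.pattern,
        "grade": s.grade,
        "native_grade": s.native_grade,
        "orifice_length_mm": geom.orifice_length,
        "min_passage_mm": geom.min_passage,
        "native_passage_mm": geom.native_passage,
        "open_orifice_fraction": 1.0 - s.grade,
        "domain_area_mm2": float(geom.polygon.area),
    }
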