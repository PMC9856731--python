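"""Thin-wire figure-8 coil model and Biot–Savart vector potential.

The coil is two coplanar wings of concentric circular loops (default nine
per wing, diameters 55–92 mm, matching a standard commercial figure-8
coil), tangent to each other at the placement point and wound in opposite
senses so the currents are co-directed under the center.  Each loop is
discretized into straight segments and the time derivative of the
magnetic vector potential is summed with midpoint quadrature,

    dA/dt(r) = (mu0 * dI/dt / 4 pi) * sum_k dl_k / |r - r_k|,

which is the quantity entering the quasi-static scalar-potential equation.
Stimulator intensity scales dI/dt linearly: 100% of maximum stimulator
output (%MSO) corresponds to 174 A/us by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "CoilModel",
    "CoilPlacement",
    "coil_wire_path",
    "wire_segments",
    "biot_savart_dAdt",
    "biot_savart_A",
    "vector_potential",
    "placement_grid",
    "write_placements",
    "read_placements",
]

MU0_OVER_4PI = 1e-7  # T m / A, mu0 = 4 pi x 1e-7 exactly


@dataclass(frozen=True)
class CoilModel:
    """Thin-wire figure-8 coil geometry and stimulator scaling."""

    loops_per_wing: int = 9
    inner_diameter_mm: float = 55.0
    outer_diameter_mm: float = 92.0
    segments_per_loop: int = 72
    didt_at_100pct: float = 174.0  # A/us at 100 %MSO
    #: height of the windings above the scalp contact point (coil casing)
    standoff_mm: float = 2.0

    def loop_radii_mm(self) -> np.ndarray:
        """Evenly spaced loop radii from the inner to the outer diameter."""
        return np.linspace(
            self.inner_diameter_mm / 2.0,
            self.outer_diameter_mm / 2.0,
            self.loops_per_wing,
        )

    def didt(self, intensity_pct_mso: float) -> float:
        """Coil current time derivative (A/us) at a stimulator intensity."""
        return self.didt_at_100pct * intensity_pct_mso / 100.0


@dataclass(frozen=True)
class CoilPlacement:
    """Rigid coil pose plus stimulator intensity.

    The triad is (current direction under the coil center, handle
    direction, outward coil normal) and must be right-handed orthonormal.
    """

    position: tuple[float, float, float]
    current_dir: tuple[float, float, float]
    handle_dir: tuple[float, float, float]
    normal: tuple[float, float, float]
    intensity_pct_mso: float = 55.0
    placement_id: str = ""

    def __post_init__(self) -> None:
        triad = self.triad()
        if not np.allclose(triad @ triad.T, np.eye(3), atol=1e-9):
            raise ValueError("placement triad is not orthonormal")
        if np.linalg.det(triad) < 0:
            raise ValueError("placement triad must be right-handed (det +1)")
        if not (0.0 < self.intensity_pct_mso <= 100.0):
            raise ValueError("intensity_pct_mso must lie in (0, 100]")

    @classmethod
    def from_vectors(
        cls,
        position: np.ndarray,
        current_dir: np.ndarray,
        normal: np.ndarray,
        intensity_pct_mso: float = 55.0,
        placement_id: str = "",
    ) -> "CoilPlacement":
        """Build a placement from position, current direction and normal.

        The current direction is re-orthogonalized against the normal and
        the handle completes the right-handed triad (h = n x c).
        """
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        c = np.asarray(current_dir, dtype=float)
        c = c - n * (c @ n)
        nc = np.linalg.norm(c)
        if nc < 1e-12:
            raise ValueError("current direction is parallel to the coil normal")
        c = c / nc
        h = np.cross(n, c)
        return cls(
            position=tuple(np.asarray(position, dtype=float)),
            current_dir=tuple(c),
            handle_dir=tuple(h),
            normal=tuple(n),
            intensity_pct_mso=intensity_pct_mso,
            placement_id=placement_id,
        )

    def triad(self) -> np.ndarray:
        return np.array([self.current_dir, self.handle_dir, self.normal], dtype=float)


# ---------------------------------------------------------------------------
# wire geometry
# ---------------------------------------------------------------------------


def coil_wire_path(
    coil: CoilModel, placement: CoilPlacement, standoff_mm: float | None = None
) -> list[np.ndarray]:
    """Closed wire polylines (world mm) of both wings, winding encoded in order.

    Returns ``2 * loops_per_wing`` arrays of shape (segments_per_loop + 1, 3);
    the last point of each closes the loop.  Wing planes coincide with the
    coil plane (normal = placement normal, offset ``standoff_mm`` along it,
    defaulting to the coil casing standoff) and the wings are tangent at the
    placement position.  Winding senses are opposite so the currents under
    the center are co-directed along the placement's current direction.
    """
    if standoff_mm is None:
        standoff_mm = coil.standoff_mm
    c = np.asarray(placement.current_dir)
    h = np.asarray(placement.handle_dir)
    n = np.asarray(placement.normal)
    center = np.asarray(placement.position, dtype=float) + standoff_mm * n
    r_out = coil.outer_diameter_mm / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, coil.segments_per_loop + 1)

    loops: list[np.ndarray] = []
    for wing_sign in (+1.0, -1.0):
        wing_center = center + wing_sign * r_out * h
        # e2 chosen so the tangent at the point nearest the center is +c
        e1, e2 = h, -wing_sign * c
        for radius in coil.loop_radii_mm():
            pts = (
                wing_center[None, :]
                + radius * np.cos(theta)[:, None] * e1[None, :]
                + radius * np.sin(theta)[:, None] * e2[None, :]
            )
            loops.append(pts)
    return loops


def wire_segments(
    coil: CoilModel, placement: CoilPlacement, standoff_mm: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Segment midpoints and directed lengths (world mm) of the full coil."""
    mids, dls = [], []
    for pts in coil_wire_path(coil, placement, standoff_mm):
        mids.append(0.5 * (pts[:-1] + pts[1:]))
        dls.append(pts[1:] - pts[:-1])
    return np.concatenate(mids), np.concatenate(dls)


# ---------------------------------------------------------------------------
# Biot-Savart quadrature
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _bs_sum(points, mids, dls):  # pragma: no cover - compiled
        n_pts = points.shape[0]
        n_seg = mids.shape[0]
        out = np.zeros((n_pts, 3))
        min_d = 1e30
        for i in range(n_pts):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            ax = ay = az = 0.0
            for k in range(n_seg):
                dx = px - mids[k, 0]
                dy = py - mids[k, 1]
                dz = pz - mids[k, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                if d < min_d:
                    min_d = d
                inv = 1.0 / d
                ax += dls[k, 0] * inv
                ay += dls[k, 1] * inv
                az += dls[k, 2] * inv
            out[i, 0] = ax
            out[i, 1] = ay
            out[i, 2] = az
        return out, min_d

else:  # pragma: no cover - numba is a declared dependency

    def _bs_sum(points, mids, dls):
        out = np.zeros((points.shape[0], 3))
        min_d = np.inf
        chunk = 2000
        for lo in range(0, points.shape[0], chunk):
            p = points[lo : lo + chunk]
            diff = p[:, None, :] - mids[None, :, :]
            d = np.sqrt((diff * diff).sum(-1))
            min_d = min(min_d, float(d.min()))
            out[lo : lo + chunk] = (dls[None, :, :] / d[:, :, None]).sum(1)
        return out, min_d


def _point_segment_distance(
    points: np.ndarray, mids: np.ndarray, dls: np.ndarray
) -> np.ndarray:
    """Exact minimum distance from each point to any wire segment (chunked)."""
    a = mids - 0.5 * dls
    out = np.empty(points.shape[0])
    L2 = (dls * dls).sum(1)
    chunk = max(1, 10_000_000 // max(len(mids), 1))
    for lo in range(0, points.shape[0], chunk):
        p = points[lo : lo + chunk]
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip((ap * dls[None, :, :]).sum(-1) / L2[None, :], 0.0, 1.0)
        closest = a[None, :, :] + t[:, :, None] * dls[None, :, :]
        d = np.linalg.norm(p[:, None, :] - closest, axis=-1)
        out[lo : lo + chunk] = d.min(1)
    return out


def biot_savart_dAdt(
    seg_mid_mm: np.ndarray,
    seg_dl_mm: np.ndarray,
    points_mm: np.ndarray,
    didt_A_per_us: float,
    guard_mm: float = 1.0,
) -> np.ndarray:
    """dA/dt (V/m) at field points for an arbitrary segmented wire path.

    The mm units of the segment lengths and the distances cancel, so the
    quadrature is evaluated directly in mm.  Points closer to the wire than
    ``guard_mm`` (exact point-to-segment distance) are rejected; the cheap
    midpoint distance from the summation triggers the exact check only for
    candidate-close points.
    """
    points = np.ascontiguousarray(np.atleast_2d(points_mm), dtype=float)
    mids = np.ascontiguousarray(seg_mid_mm, dtype=float)
    dls = np.ascontiguousarray(seg_dl_mm, dtype=float)
    acc, min_d = _bs_sum(points, mids, dls)
    half_seg = 0.5 * np.linalg.norm(dls, axis=1).max()
    if guard_mm > 0 and min_d < guard_mm + half_seg:
        # pre-filter with a chunked subsampled-midpoint distance, then check
        # the exact point-to-segment distance on candidate-close points only
        sub = mids[::7]
        mid_d = np.empty(len(points))
        chunk = max(1, 20_000_000 // max(len(sub), 1))
        for lo in range(0, len(points), chunk):
            p = points[lo : lo + chunk]
            mid_d[lo : lo + chunk] = np.sqrt(
                ((p[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
            ).min(1)
        cand = np.flatnonzero(mid_d < guard_mm + 8 * half_seg)
        if cand.size:
            d = _point_segment_distance(points[cand], mids, dls)
            if d.min() < guard_mm:
                worst = cand[int(np.argmin(d))]
                raise ValueError(
                    f"field point {points[worst].tolist()} mm is {d.min():.3f} mm "
                    f"from the coil wire (guard {guard_mm} mm)"
                )
    # mu0/4pi * (A/us -> A/s) = 0.1 * didt, distances cancel in mm
    return (MU0_OVER_4PI * didt_A_per_us * 1e6) * acc


def biot_savart_A(
    seg_mid_mm: np.ndarray,
    seg_dl_mm: np.ndarray,
    points_mm: np.ndarray,
    current_A: float,
    guard_mm: float = 1.0,
) -> np.ndarray:
    """Static vector potential A (T m) of the wire path carrying ``current_A``."""
    points = np.ascontiguousarray(np.atleast_2d(points_mm), dtype=float)
    acc, min_d = _bs_sum(
        points,
        np.ascontiguousarray(seg_mid_mm, dtype=float),
        np.ascontiguousarray(seg_dl_mm, dtype=float),
    )
    if min_d < guard_mm:
        raise ValueError(f"field point within {guard_mm} mm of the wire")
    return MU0_OVER_4PI * current_A * acc


def vector_potential(
    coil: CoilModel,
    placement: CoilPlacement,
    points_mm: np.ndarray,
    didt_A_per_us: float | None = None,
    guard_mm: float = 1.0,
    standoff_mm: float | None = None,
) -> np.ndarray:
    """dA/dt (V/m) of the placed figure-8 coil at the given world points.

    ``didt_A_per_us`` defaults to the placement intensity scaled from the
    coil's 100 %MSO rating.
    """
    if didt_A_per_us is None:
        didt_A_per_us = coil.didt(placement.intensity_pct_mso)
    mids, dls = wire_segments(coil, placement, standoff_mm)
    return biot_savart_dAdt(mids, dls, points_mm, didt_A_per_us, guard_mm)


class CoilFieldCache:
    """Coil-frame dA/dt lookup table shared across placements.

    The dA/dt pattern of a rigid coil is invariant under rigid motion, so
    it is evaluated once on a regular grid in the coil frame (origin at the
    scalp contact point, axes = placement triad) and trilinearly
    interpolated — with the appropriate rotation of the vectors — for every
    placement.  ``extent_mm`` must cover the head as seen from any scalp
    contact point; interpolation error at cortical depth is well below the
    discretization error of the field solve (see the convergence test).
    """

    def __init__(
        self,
        coil: CoilModel,
        extent_mm: float,
        spacing_mm: float = 1.5,
        standoff_mm: float | None = None,
    ):
        self.coil = coil
        self.spacing = spacing_mm
        # local box: head sphere of radius `extent` tangent at the origin
        self.origin = np.array(
            [-(extent_mm + 5.0), -(extent_mm + 5.0), -(2.0 * extent_mm + 5.0)]
        )
        top = 2.0 + (standoff_mm if standoff_mm is not None else coil.standoff_mm)
        n_xy = int(np.ceil((2 * extent_mm + 10.0) / spacing_mm)) + 1
        n_z = int(np.ceil((2 * extent_mm + 7.0 + top) / spacing_mm)) + 1
        ref = CoilPlacement.from_vectors(
            np.zeros(3), [1.0, 0, 0], [0, 0, 1.0], intensity_pct_mso=100.0
        )
        mids, dls = wire_segments(coil, ref, standoff_mm)
        ax = [self.origin[i] + spacing_mm * np.arange((n_xy, n_xy, n_z)[i]) for i in range(3)]
        pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        # unit-didt basis field; scaled per query.  No singularity guard:
        # table nodes adjacent to the wire are never queried (all queries
        # lie inside the head, below the casing standoff)
        self.table = biot_savart_dAdt(mids, dls, pts, 1.0, guard_mm=0.0).reshape(
            n_xy, n_xy, n_z, 3
        )

    def evaluate(
        self,
        placement: CoilPlacement,
        points_mm: np.ndarray,
        didt_A_per_us: float | None = None,
    ) -> np.ndarray:
        from scipy import ndimage

        if didt_A_per_us is None:
            didt_A_per_us = self.coil.didt(placement.intensity_pct_mso)
        R = placement.triad().T  # columns c, h, n: local -> world
        local = (np.atleast_2d(points_mm) - np.asarray(placement.position)) @ R
        idx = (local - self.origin) / self.spacing
        vec_local = np.stack(
            [
                ndimage.map_coordinates(self.table[..., i], idx.T, order=1)
                for i in range(3)
            ],
            axis=1,
        )
        return didt_A_per_us * (vec_local @ R.T)


# ---------------------------------------------------------------------------
# placement grid
# ---------------------------------------------------------------------------


def placement_grid(
    sulcus_polyline_mm: np.ndarray,
    n_anchors: int = 8,
    spacing_mm: float = 5.0,
    shifts_mm: tuple[float, ...] = (-5.0, 0.0, 5.0),
    intensity_pct_mso: float = 55.0,
    projector=None,
) -> list[CoilPlacement]:
    """Sulcus-aligned coil placement grid.

    ``n_anchors`` points are placed at ``spacing_mm`` intervals along the
    scalp trace of the sulcus, centered on its midpoint; each anchor is then
    shifted by every entry of ``shifts_mm`` along the induced-current
    direction (perpendicular to the local sulcus tangent, tangent to the
    scalp).  The default protocol (8 anchors x 3 shifts at 5 mm) yields 24
    placements at a density of 4 stimuli/cm^2.

    ``projector`` maps a point to ``(point_on_scalp, outward_normal)``;
    without one, points are assumed to lie on a scalp sphere centered at
    the origin.
    """
    poly = np.asarray(sulcus_polyline_mm, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValueError("sulcus polyline must contain at least two points")
    seg = np.diff(poly, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    if np.all(seglen < 1e-9):
        raise ValueError("degenerate sulcus polyline (zero length)")
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    needed = (n_anchors - 1) * spacing_mm
    if needed > total + 1e-9:
        raise ValueError(
            f"polyline length {total:.1f} mm too short for {n_anchors} anchors "
            f"at {spacing_mm} mm spacing ({needed:.1f} mm needed)"
        )

    if projector is None:

        def projector(p):
            u = p / np.linalg.norm(p)
            return u * np.linalg.norm(poly[0]), u

    def interp(a: float) -> tuple[np.ndarray, np.ndarray]:
        j = int(np.clip(np.searchsorted(arc, a) - 1, 0, len(seg) - 1))
        f = (a - arc[j]) / max(seglen[j], 1e-12)
        pos = poly[j] + f * seg[j]
        tan = seg[j] / max(seglen[j], 1e-12)
        return pos, tan

    mid = total / 2.0
    placements: list[CoilPlacement] = []
    for ai in range(n_anchors):
        a = mid + (ai - (n_anchors - 1) / 2.0) * spacing_mm
        anchor, tangent = interp(a)
        anchor, normal = projector(anchor)
        current = np.cross(tangent, normal)
        current /= np.linalg.norm(current)
        for si, shift in enumerate(shifts_mm):
            p = anchor + shift * current
            p, n_loc = projector(p)
            placements.append(
                CoilPlacement.from_vectors(
                    position=p,
                    current_dir=current,
                    normal=n_loc,
                    intensity_pct_mso=intensity_pct_mso,
                    placement_id=f"a{ai}s{si}",
                )
            )
    return placements


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_CSV_COLS = [
    "id", "x", "y", "z",
    "cx", "cy", "cz", "hx", "hy", "hz", "nx", "ny", "nz",
    "pct_mso",
]


def write_placements(placements: list[CoilPlacement], path: str | Path) -> None:
    rows = [
        [p.placement_id, *p.position, *p.current_dir, *p.handle_dir, *p.normal,
         p.intensity_pct_mso]
        for p in placements
    ]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def read_placements(path: str | Path) -> list[CoilPlacement]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"placement table missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            CoilPlacement(
                position=(r.x, r.y, r.z),
                current_dir=(r.cx, r.cy, r.cz),
                handle_dir=(r.hx, r.hy, r.hz),
                normal=(r.nx, r.ny, r.nz),
                intensity_pct_mso=float(r.pct_mso),
                placement_id=str(r.id),
            )
        )
    return out
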