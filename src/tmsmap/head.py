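"""Synthetic layered head models with a central-sulcus-like cortical fold.

The generator replaces individualized MRI-derived head models with a
five-tissue spherical phantom (skin, skull, CSF, gray matter, white
matter) whose gray/white boundaries carry a single sinusoidal
invagination — the minimal geometry that distinguishes a gyral crown
from a sulcal wall and lip.  Ground-truth muscle representation sites
are planted on the fold lip, mirroring the arrangement of two adjacent
intrinsic hand muscles on the precentral gyrus.

Coordinates are world RAS in mm, the head is centered at the origin and
the fold sits at the "north pole" (+z).  Voxel indices are 0-based and
the affine maps corner-centered indices to world coordinates, i.e. the
center of voxel ``(i, j, k)`` is at ``affine @ (i+0.5, j+0.5, k+0.5, 1)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "HeadGeometry",
    "VoxelHeadModel",
    "CorticalSurface",
    "SyntheticSubject",
    "build_synthetic_head",
    "extract_surface",
    "paint_regions",
    "write_model",
    "read_model",
    "save_subject",
    "load_subject",
    "REGION_NAMES",
    "DEFAULT_CONDUCTIVITIES",
]

#: Literature isotropic conductivities in S/m (config-exposed; the mapping
#: method itself is insensitive to the exact assignment because only relative
#: field values enter the localization).
DEFAULT_CONDUCTIVITIES: dict[int, float] = {
    1: 0.465,   # skin
    2: 0.010,   # skull (compact-bone average)
    3: 1.654,   # cerebrospinal fluid
    4: 0.275,   # gray matter
    5: 0.126,   # white matter
}

LABEL_NAMES = {0: "background", 1: "skin", 2: "skull", 3: "CSF", 4: "gray", 5: "white"}

#: Region codes painted on the cortical surface by the generator.
REGION_NAMES = {0: "other", 1: "fundus", 2: "wall", 3: "lip", 4: "crown"}


class GeometryError(ValueError):
    """Raised when a geometry specification violates layer nesting."""


# ---------------------------------------------------------------------------
# geometry specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadGeometry:
    """Parameters of the synthetic head phantom.

    The phantom is anatomical scale: the sphere approximates the superior
    cranial dome of an adult head, so that the fixed-size figure-8 coil
    sees realistic coil-to-cortex distances and a realistic field falloff
    relative to cortical dimensions — both of which the focality of the
    multiplicative mapping depends on.  Layer thicknesses and the fold
    geometry (a central-sulcus-like groove of ~15 mm depth and ~16 mm
    width over a ~40 mm hand-knob segment) follow adult anatomy.

    Attributes
    ----------
    skin_radius_mm : outer radius of the scalp sphere.
    skin_thickness_mm, skull_thickness_mm, csf_thickness_mm,
    cortical_thickness_mm : radial layer thicknesses; everything inside the
        cortex is white matter.
    fold_amplitude_mm : depth of the sulcal invagination (0 disables it).
    fold_wavelength_mm : full wavelength of the raised-cosine groove; the
        groove occupies ``|s| <= wavelength/2`` across the fold.
    fold_length_mm : extent of the groove along the sulcus.
    fold_taper_mm : smoothness of the groove ends along the sulcus.
    voxel_size_mm : isotropic voxel edge length (>= 0.4).
    pad_mm : background (air) padding beyond the scalp.
    truth_separation_mm : distance between the two planted muscle sites
        along the sulcus (FDI-analog lateral, ADM-analog medial).
    truth_lip_fraction : across-fold coordinate of the truth sites as a
        fraction of the wavelength (0.45 puts them on the lip).
    """

    skin_radius_mm: float = 78.0
    skin_thickness_mm: float = 6.0
    skull_thickness_mm: float = 6.5
    csf_thickness_mm: float = 2.5
    cortical_thickness_mm: float = 3.0
    fold_amplitude_mm: float = 15.0
    fold_wavelength_mm: float = 16.0
    fold_length_mm: float = 40.0
    fold_taper_mm: float = 3.0
    voxel_size_mm: float = 1.0
    pad_mm: float = 3.0
    truth_separation_mm: float = 3.0
    truth_lip_fraction: float = 0.45
    conductivities: tuple[tuple[int, float], ...] = tuple(
        sorted(DEFAULT_CONDUCTIVITIES.items())
    )

    # derived outer radii, outermost to innermost
    @property
    def skull_radius_mm(self) -> float:
        return self.skin_radius_mm - self.skin_thickness_mm

    @property
    def csf_radius_mm(self) -> float:
        return self.skull_radius_mm - self.skull_thickness_mm

    @property
    def gray_radius_mm(self) -> float:
        return self.csf_radius_mm - self.csf_thickness_mm

    @property
    def white_radius_mm(self) -> float:
        return self.gray_radius_mm - self.cortical_thickness_mm

    def conductivity_table(self) -> dict[int, float]:
        return dict(self.conductivities)

    def validate(self) -> None:
        if self.voxel_size_mm < 0.4:
            raise GeometryError(
                f"voxel_size_mm={self.voxel_size_mm} below the 0.4 mm minimum"
            )
        radii = [
            ("skin", self.skin_radius_mm),
            ("skull", self.skull_radius_mm),
            ("CSF", self.csf_radius_mm),
            ("gray", self.gray_radius_mm),
            ("white", self.white_radius_mm),
        ]
        for (outer_name, outer_r), (inner_name, inner_r) in zip(radii, radii[1:]):
            if not 0.0 < inner_r < outer_r:
                raise GeometryError(
                    f"layers not nested: {inner_name} (r={inner_r:.2f}) must lie "
                    f"strictly inside {outer_name} (r={outer_r:.2f}) with a "
                    "positive radius"
                )
        if self.white_radius_mm <= self.fold_amplitude_mm:
            raise GeometryError(
                "layers not nested: fold amplitude "
                f"{self.fold_amplitude_mm} exceeds the white-matter radius "
                f"{self.white_radius_mm:.2f}"
            )
        if self.fold_amplitude_mm < 0 or self.fold_wavelength_mm <= 0:
            raise GeometryError("fold amplitude must be >= 0 and wavelength > 0")

    # -- fold parameterization -------------------------------------------
    # (s, t): geodesic-like surface coordinates at the base gray radius.
    # s is the signed arc distance across the sulcus (from the great circle
    # x = 0), t the arc distance along the sulcus (from the +z pole).

    def surface_coords(self, unit_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map unit direction vectors to fold coordinates ``(s, t)`` in mm."""
        u = np.asarray(unit_dirs, dtype=float)
        rg = self.gray_radius_mm
        s = rg * np.arcsin(np.clip(u[..., 0], -1.0, 1.0))
        t = rg * np.arctan2(u[..., 1], u[..., 2])
        return s, t

    def direction_from_coords(self, s: float, t: float) -> np.ndarray:
        rg = self.gray_radius_mm
        sx = np.sin(s / rg)
        c = np.cos(s / rg)
        return np.array([sx, c * np.sin(t / rg), c * np.cos(t / rg)])

    def fold_displacement(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Inward radial displacement (<= 0) of the cortical boundaries."""
        a = self.fold_amplitude_mm
        if a == 0.0:
            return np.zeros(np.broadcast(s, t).shape)
        lam = self.fold_wavelength_mm
        across = np.where(
            np.abs(s) <= lam / 2.0,
            0.5 * (1.0 + np.cos(2.0 * np.pi * s / lam)),
            0.0,
        )
        half_len = self.fold_length_mm / 2.0
        tau = max(self.fold_taper_mm, 1e-6)
        along = 0.5 * (np.tanh((t + half_len) / tau) - np.tanh((t - half_len) / tau))
        return -a * across * along

    def fold_slope(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Magnitude of the surface gradient of the fold displacement."""
        a = self.fold_amplitude_mm
        if a == 0.0:
            return np.zeros(np.broadcast(s, t).shape)
        lam = self.fold_wavelength_mm
        half_len = self.fold_length_mm / 2.0
        tau = max(self.fold_taper_mm, 1e-6)
        across = np.where(
            np.abs(s) <= lam / 2.0,
            0.5 * (1.0 + np.cos(2.0 * np.pi * s / lam)),
            0.0,
        )
        d_across = np.where(
            np.abs(s) <= lam / 2.0,
            -0.5 * (2.0 * np.pi / lam) * np.sin(2.0 * np.pi * s / lam),
            0.0,
        )
        along = 0.5 * (np.tanh((t + half_len) / tau) - np.tanh((t - half_len) / tau))
        d_along = (0.5 / tau) * (
            1.0 / np.cosh((t + half_len) / tau) ** 2
            - 1.0 / np.cosh((t - half_len) / tau) ** 2
        )
        return a * np.hypot(d_across * along, across * d_along)

    def radial_cortical_thickness(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Radial extent of the cortical ribbon.

        The ribbon has constant thickness perpendicular to the (folded)
        surface; on a slanted sulcal wall the radial crossing is longer by
        the slant factor sqrt(1 + |grad delta|^2).
        """
        return self.cortical_thickness_mm * np.sqrt(1.0 + self.fold_slope(s, t) ** 2)

    def region_of(self, s: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Paint fold regions: fundus / wall / lip / crown (see REGION_NAMES)."""
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        lam = self.fold_wavelength_mm
        a = np.abs(s)
        near = (np.abs(t) <= self.fold_length_mm / 2.0) & (a <= 1.6 * lam)
        region = np.zeros(s.shape, dtype=np.int8)
        region[near & (a < 0.10 * lam)] = 1
        region[near & (a >= 0.10 * lam) & (a < 0.38 * lam)] = 2
        region[near & (a >= 0.38 * lam) & (a < 0.60 * lam)] = 3
        region[near & (a >= 0.60 * lam)] = 4
        return region


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VoxelHeadModel:
    """Labeled conductivity volume on a regular grid.

    ``labels`` holds 0=background, 1=skin, 2=skull, 3=CSF, 4=gray, 5=white;
    ``conductivity_table`` maps nonzero labels to σ in S/m.
    """

    labels: np.ndarray
    voxel_size_mm: float
    affine: np.ndarray
    conductivity_table: dict[int, float]

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def sigma_volume(self) -> np.ndarray:
        """Per-voxel conductivity in S/m (0 in background)."""
        lut = np.zeros(int(self.labels.max()) + 1)
        for lab, sig in self.conductivity_table.items():
            if lab < lut.size:
                lut[lab] = sig
        return lut[self.labels]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape dims + (3,)."""
        nx, ny, nz = self.dims
        idx = np.stack(
            np.meshgrid(
                np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
            ),
            axis=-1,
        ).astype(float) + 0.5
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel-center indices of world points (for interpolation)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3] - 0.5

    def validate(self) -> None:
        labels_present = np.unique(self.labels)
        for lab in labels_present:
            if lab == 0:
                continue
            sigma = self.conductivity_table.get(int(lab))
            if sigma is None:
                raise ValueError(f"label {int(lab)} has no conductivity")
            if sigma <= 0:
                raise ValueError(f"label {int(lab)} has non-positive conductivity")
        if self.conductivity_table.get(0, 0.0) != 0.0:
            raise ValueError("background (label 0) must have zero conductivity")
        shell = np.concatenate(
            [
                self.labels[[0, -1], :, :].ravel(),
                self.labels[:, [0, -1], :].ravel(),
                self.labels[:, :, [0, -1]].ravel(),
            ]
        )
        if np.any(shell != 0):
            raise ValueError("outermost voxel shell must be background (insulating)")
        gray = self.labels == 4
        if gray.any():
            _, n_comp = ndimage.label(gray)
            if n_comp != 1:
                raise ValueError(f"gray matter splits into {n_comp} components")
            dil = ndimage.binary_dilation(gray)
            if not np.any(dil & (self.labels == 3)):
                raise ValueError("gray matter does not adjoin CSF")
            if not np.any(dil & (self.labels == 5)):
                raise ValueError("gray matter does not adjoin white matter")


@dataclass
class CorticalSurface:
    """Triangulated cortical surface in world coordinates (mm).

    ``vertex_area_mm2`` is the barycentric (one-third per incident triangle)
    vertex area, so the vertex areas sum exactly to the mesh area.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_normals: np.ndarray
    vertex_area_mm2: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def area_mm2(self) -> float:
        return float(self.vertex_area_mm2.sum())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def validate(self) -> None:
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("vertex normals are not unit length")
        if self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices:
            raise ValueError("triangle indices out of range")
        tot = self.triangle_areas().sum()
        if not np.isclose(tot, self.area_mm2, rtol=1e-6):
            raise ValueError("vertex areas inconsistent with mesh area")


def _vertex_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    cr = np.cross(
        vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
        vertices[triangles[:, 2]] - vertices[triangles[:, 0]],
    )
    tri_area = 0.5 * np.linalg.norm(cr, axis=1)
    va = np.zeros(len(vertices))
    for col in range(3):
        np.add.at(va, triangles[:, col], tri_area / 3.0)
    return va


@dataclass
class SyntheticSubject:
    """A synthetic participant: head model, cortex, and planted ground truth.

    ``truth_sites`` maps a muscle label (``"FDI"``, ``"ADM"``) to the vertex
    index of its cortical representation center; ``sigmoid_truth`` holds the
    (a, b, c) recruitment-curve parameters used to generate MEPs (in mV,
    (V/m)^-1 and V/m).  The stored parameters are placeholders until
    :func:`tmsmap.dose_response.calibrate_sigmoid_truth` anchors them to the
    electric fields actually induced in this head.
    """

    head: VoxelHeadModel
    surface: CorticalSurface
    geometry: HeadGeometry
    truth_sites: dict[str, int]
    sigmoid_truth: dict[str, tuple[float, float, float]]
    noise_sigma_log: float = 0.3
    seed: int = 0
    regions: np.ndarray | None = None
    sampling_depth_mm: float = 0.8

    # -- scalp helpers ----------------------------------------------------
    def scalp_project(self, point_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Radially project a point onto the scalp; return (point, outward normal)."""
        p = np.asarray(point_mm, dtype=float)
        r = np.linalg.norm(p)
        if r == 0:
            raise ValueError("cannot project the head center onto the scalp")
        u = p / r
        return u * self.geometry.skin_radius_mm, u

    def sulcus_scalp_polyline(
        self, half_length_mm: float = 25.0, n_points: int = 51
    ) -> np.ndarray:
        """Scalp trace of the sulcus (the great arc above the fold line)."""
        rs = self.geometry.skin_radius_mm
        ang = np.linspace(-half_length_mm, half_length_mm, n_points) / rs
        return rs * np.stack(
            [np.zeros_like(ang), np.sin(ang), np.cos(ang)], axis=1
        )

    def truth_position(self, muscle: str) -> np.ndarray:
        return self.surface.vertices[self.truth_sites[muscle]]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def build_synthetic_head(
    geometry: HeadGeometry | None = None,
    seed: int = 0,
    noise_sigma_log: float = 0.3,
    sampling_depth_mm: float = 0.8,
) -> SyntheticSubject:
    """Generate a synthetic subject from a geometry specification.

    The label volume is evaluated analytically at voxel centers, the
    cortical sampling surface is extracted ``sampling_depth_mm`` inside the
    gray-matter outer boundary, fold regions are painted on its vertices,
    and two ground-truth muscle sites are planted on the fold lip.  The
    construction is fully deterministic: identical geometry and seed yield
    bit-identical subjects.
    """
    geom = geometry or HeadGeometry()
    geom.validate()

    h = geom.voxel_size_mm
    half_extent = geom.skin_radius_mm + geom.pad_mm
    n = int(np.ceil(2.0 * half_extent / h))
    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = -0.5 * n * h  # grid centered on the origin

    coords_1d = (np.arange(n) + 0.5) * h - 0.5 * n * h
    gx, gy, gz = np.meshgrid(coords_1d, coords_1d, coords_1d, indexing="ij")
    r = np.sqrt(gx * gx + gy * gy + gz * gz)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.stack([gx, gy, gz], axis=-1) / np.maximum(r, 1e-12)[..., None]
    s, t = geom.surface_coords(u)
    delta = geom.fold_displacement(s, t)

    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[r < geom.skin_radius_mm] = 1
    labels[r < geom.skull_radius_mm] = 2
    labels[r < geom.csf_radius_mm] = 3
    labels[r < geom.gray_radius_mm + delta] = 4
    labels[r < geom.gray_radius_mm + delta - geom.radial_cortical_thickness(s, t)] = 5
    # enforce the insulating outer shell explicitly
    labels[[0, -1], :, :] = 0
    labels[:, [0, -1], :] = 0
    labels[:, :, [0, -1]] = 0

    head = VoxelHeadModel(
        labels=labels,
        voxel_size_mm=h,
        affine=affine,
        conductivity_table=geom.conductivity_table(),
    )
    head.validate()

    surface = extract_surface(head, depth_mm=sampling_depth_mm)

    vu = surface.vertices / np.linalg.norm(surface.vertices, axis=1, keepdims=True)
    vs, vt = geom.surface_coords(vu)
    regions = geom.region_of(vs, vt)

    # plant the two truth sites on the fold lip, offset along the sulcus
    tree = cKDTree(surface.vertices)
    s_truth = geom.truth_lip_fraction * geom.fold_wavelength_mm
    truth_sites: dict[str, int] = {}
    taken: set[int] = set()
    for muscle, t_off in (
        ("FDI", -geom.truth_separation_mm / 2.0),
        ("ADM", +geom.truth_separation_mm / 2.0),
    ):
        u_site = geom.direction_from_coords(s_truth, t_off)
        dlt = float(geom.fold_displacement(np.array(s_truth), np.array(t_off)))
        target = u_site * (geom.gray_radius_mm + dlt - sampling_depth_mm)
        _, cand = tree.query(target, k=4)
        idx = next(int(i) for i in np.atleast_1d(cand) if int(i) not in taken)
        taken.add(idx)
        truth_sites[muscle] = idx

    # placeholder recruitment parameters; calibrated against solved fields
    # by the dose-response module before MEP simulation
    sigmoid_truth = {m: (2.0, 0.1, 200.0) for m in truth_sites}

    return SyntheticSubject(
        head=head,
        surface=surface,
        geometry=geom,
        truth_sites=truth_sites,
        sigmoid_truth=sigmoid_truth,
        noise_sigma_log=noise_sigma_log,
        seed=seed,
        regions=regions,
        sampling_depth_mm=sampling_depth_mm,
    )


def paint_regions(subject: SyntheticSubject) -> np.ndarray:
    """Fold-region code per surface vertex (see :data:`REGION_NAMES`)."""
    if subject.regions is not None:
        return subject.regions
    vu = subject.surface.vertices / np.linalg.norm(
        subject.surface.vertices, axis=1, keepdims=True
    )
    s, t = subject.geometry.surface_coords(vu)
    return subject.geometry.region_of(s, t)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------


def extract_surface(head: VoxelHeadModel, depth_mm: float = 0.8) -> CorticalSurface:
    """Extract the cortical sampling surface ``depth_mm`` inside gray matter.

    A signed distance to the gray-matter outer boundary (negative inside the
    brain) is built from Euclidean distance transforms of the gray+white
    compartment, lightly smoothed, and contoured with marching cubes at
    level ``-depth_mm``.  Normals are the (normalized) signed-distance
    gradient, hence point outward toward the CSF.
    """
    if depth_mm < 0:
        raise ValueError("depth_mm must be >= 0")
    h = head.voxel_size_mm
    brain = np.isin(head.labels, (4, 5))
    if not brain.any():
        raise ValueError("head model contains no gray/white matter")

    # minimum cortical thickness at the white/gray interface
    d_out = ndimage.distance_transform_edt(brain, sampling=h)
    white = head.labels == 5
    interface = white & ndimage.binary_dilation(head.labels == 4)
    if interface.any():
        thick = d_out[interface]
        min_thick = float(thick.min())
        if depth_mm >= min_thick:
            worst = np.argwhere(interface)[int(np.argmin(thick))]
            world = (worst + 0.5) @ head.affine[:3, :3].T + head.affine[:3, 3]
            raise ValueError(
                f"depth {depth_mm} mm exceeds the cortical thickness "
                f"({min_thick:.2f} mm near {np.round(world, 1).tolist()} mm)"
            )

    d_in = ndimage.distance_transform_edt(~brain, sampling=h)
    sdist_raw = d_in - d_out  # positive outside the brain, increases outward
    # 1.2 mm level-set smoothing minimizes the RMS distance error of the
    # extracted surface against the analytic boundary of the synthetic
    # phantom (it averages out the ~h/2 staircase noise of the distance
    # transform without rounding the fold, whose features are >= several mm)
    sdist = ndimage.gaussian_filter(sdist_raw, sigma=1.2 / h)

    verts_idx, faces, _, _ = measure.marching_cubes(sdist, level=-depth_mm)
    # marching-cubes vertices are in voxel-center index units
    verts = (verts_idx + 0.5) @ head.affine[:3, :3].T + head.affine[:3, 3]

    # normals from a voxel-proportionally smoothed field (1.4 h): the
    # smallest scale that suppresses the staircase facets of the distance
    # gradient, so the normal error vanishes under grid refinement
    sdist_n = ndimage.gaussian_filter(sdist_raw, sigma=1.4)
    grad = np.stack(np.gradient(sdist_n, h), axis=-1)
    gv = np.stack(
        [
            ndimage.map_coordinates(grad[..., ax], verts_idx.T, order=1)
            for ax in range(3)
        ],
        axis=1,
    )
    norms = np.linalg.norm(gv, axis=1, keepdims=True)
    normals = gv / np.maximum(norms, 1e-12)

    faces = np.ascontiguousarray(faces.astype(np.int64))
    return CorticalSurface(
        vertices=verts,
        triangles=faces,
        vertex_normals=normals,
        vertex_area_mm2=_vertex_areas(verts, faces),
    )


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------


def write_model(
    head: VoxelHeadModel,
    surface: CorticalSurface,
    out_dir: str | Path,
    stem: str = "head",
) -> dict[str, Path]:
    """Write NIfTI labels, a binary PLY surface, and a JSON conductivity table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels": out / f"{stem}_labels.nii.gz",
        "surface": out / f"{stem}_surface.ply",
        "conductivity": out / f"{stem}_conductivity.json",
    }
    img = nib.Nifti1Image(head.labels.astype(np.int16), head.affine)
    nib.save(img, paths["labels"])
    surface.as_trimesh().export(paths["surface"], file_type="ply", encoding="binary")
    meta = {
        "voxel_size_mm": head.voxel_size_mm,
        "conductivity_S_per_m": {str(k): v for k, v in head.conductivity_table.items()},
    }
    paths["conductivity"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths


def read_model(
    labels_path: str | Path,
    surface_path: str | Path,
    conductivity_path: str | Path,
) -> tuple[VoxelHeadModel, CorticalSurface]:
    """Read a head model written by :func:`write_model` and validate it."""
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    meta = json.loads(Path(conductivity_path).read_text())
    table = {int(k): float(v) for k, v in meta["conductivity_S_per_m"].items()}
    head = VoxelHeadModel(
        labels=labels,
        voxel_size_mm=float(meta["voxel_size_mm"]),
        affine=np.asarray(img.affine, dtype=float),
        conductivity_table=table,
    )
    missing = sorted(
        int(lab) for lab in np.unique(labels) if lab != 0 and int(lab) not in table
    )
    if missing:
        raise ValueError(
            "label "
            + ", ".join(str(m) for m in missing)
            + " has no conductivity"
        )
    head.validate()

    mesh = trimesh.load(str(surface_path), process=False)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    vn = np.asarray(mesh.vertex_normals, dtype=float)
    vn = vn / np.maximum(np.linalg.norm(vn, axis=1, keepdims=True), 1e-12)
    # orient outward (away from the head center)
    flip = np.einsum("ij,ij->i", vn, verts) < 0
    vn[flip] *= -1.0
    surface = CorticalSurface(
        vertices=verts,
        triangles=faces,
        vertex_normals=vn,
        vertex_area_mm2=_vertex_areas(verts, faces),
    )
    return head, surface


def save_subject(subject: SyntheticSubject, out_dir: str | Path) -> dict[str, Path]:
    """Persist a full subject (model files plus a JSON sidecar)."""
    out = Path(out_dir)
    paths = write_model(subject.head, subject.surface, out)
    sidecar = {
        "geometry": dataclasses.asdict(subject.geometry),
        "truth_sites": subject.truth_sites,
        "sigmoid_truth": {k: list(v) for k, v in subject.sigmoid_truth.items()},
        "noise_sigma_log": subject.noise_sigma_log,
        "seed": subject.seed,
        "sampling_depth_mm": subject.sampling_depth_mm,
    }
    paths["subject"] = out / "subject.json"
    paths["subject"].write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return paths


def load_subject(out_dir: str | Path) -> SyntheticSubject:
    out = Path(out_dir)
    meta = json.loads((out / "subject.json").read_text())
    gdict = meta["geometry"]
    gdict["conductivities"] = tuple(
        (int(k), float(v)) for k, v in gdict["conductivities"]
    )
    geom = HeadGeometry(**gdict)
    head, surface = read_model(
        out / "head_labels.nii.gz",
        out / "head_surface.ply",
        out / "head_conductivity.json",
    )
    subject = SyntheticSubject(
        head=head,
        surface=surface,
        geometry=geom,
        truth_sites={k: int(v) for k, v in meta["truth_sites"].items()},
        sigmoid_truth={k: tuple(v) for k, v in meta["sigmoid_truth"].items()},
        noise_sigma_log=float(meta["noise_sigma_log"]),
        seed=int(meta["seed"]),
        sampling_depth_mm=float(meta["sampling_depth_mm"]),
    )
    subject.regions = paint_regions(subject)
    return subject
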