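"""Sampling the induced field on the cortical surface and the EF metrics.

Two scalar metrics drive the localization: the field strength |EF| and
the magnitude of the component normal to the cortical surface |EF.n|
(EF⊥).  The normal component is reported unsigned because the
multiplicative localization requires nonnegative maps; the signed value
(inward negative) is kept alongside for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .head import CorticalSurface
from .solver import EFVolume

__all__ = ["EFSurfaceMap", "sample_on_surface", "write_surface_map", "read_surface_map"]


@dataclass
class EFSurfaceMap:
    """Per-vertex induced field and metrics for one stimulus."""

    stimulus_id: str
    vectors: np.ndarray          # (V, 3) V/m
    ef_strength: np.ndarray      # |EF|
    ef_normal: np.ndarray        # |EF . n|
    ef_normal_signed: np.ndarray
    intensity_pct_mso: float

    @property
    def n_vertices(self) -> int:
        return self.vectors.shape[0]

    def metric(self, name: str) -> np.ndarray:
        if name == "strength":
            return self.ef_strength
        if name == "normal":
            return self.ef_normal
        raise ValueError(f"unknown EF metric {name!r} (use 'strength' or 'normal')")

    def scaled(self, intensity_pct_mso: float) -> "EFSurfaceMap":
        """Map at another stimulator intensity (fields are linear in dI/dt)."""
        f = intensity_pct_mso / self.intensity_pct_mso
        return EFSurfaceMap(
            stimulus_id=self.stimulus_id,
            vectors=self.vectors * f,
            ef_strength=self.ef_strength * f,
            ef_normal=self.ef_normal * f,
            ef_normal_signed=self.ef_normal_signed * f,
            intensity_pct_mso=intensity_pct_mso,
        )

    def validate(self) -> None:
        if np.any(self.ef_normal > self.ef_strength * (1 + 1e-9) + 1e-12):
            raise ValueError("ef_normal exceeds ef_strength (violates Cauchy-Schwarz)")
        if np.any(self.ef_strength < 0) or np.any(self.ef_normal < 0):
            raise ValueError("EF metrics must be nonnegative")


def sample_on_surface(
    ef: EFVolume,
    surface: CorticalSurface,
    stimulus_id: str = "",
    sample_mask: np.ndarray | None = None,
) -> EFSurfaceMap:
    """Trilinear interpolation of the field at the surface vertices.

    Every vertex must lie strictly inside conducting tissue (all eight
    surrounding voxel centers conducting); offending vertices raise with
    their count and the worst one.

    ``sample_mask`` (typically the gray+white compartment) restricts the
    interpolation support: trilinear weights of voxels outside the mask are
    dropped and renormalized.  This avoids diluting cortical values with
    CSF voxels at the staircase boundary of coarse grids — the normal field
    component is discontinuous there by current conservation.
    """
    inv = np.linalg.inv(ef.affine)
    idx = surface.vertices @ inv[:3, :3].T + inv[:3, 3] - 0.5

    inside = ndimage.map_coordinates(
        ef.conducting.astype(float), idx.T, order=1, mode="constant", cval=0.0
    )
    bad = inside < 1.0 - 1e-9
    if bad.any():
        worst = int(np.argmin(inside))
        raise ValueError(
            f"{int(bad.sum())} surface vertices lie outside the conductor; "
            f"worst at {np.round(surface.vertices[worst], 1).tolist()} mm "
            f"(conducting fraction {inside[worst]:.2f})"
        )

    if sample_mask is None:
        vec = np.stack(
            [
                ndimage.map_coordinates(ef.E[..., ax], idx.T, order=1)
                for ax in range(3)
            ],
            axis=1,
        )
    else:
        w = sample_mask.astype(float)
        wsum = ndimage.map_coordinates(w, idx.T, order=1)
        vec = np.stack(
            [
                ndimage.map_coordinates(ef.E[..., ax] * w, idx.T, order=1)
                for ax in range(3)
            ],
            axis=1,
        )
        ok = wsum > 0.05
        vec[ok] /= wsum[ok, None]
        if not ok.all():  # no masked support: fall back to plain trilinear
            fallback = np.stack(
                [
                    ndimage.map_coordinates(ef.E[..., ax], idx[~ok].T, order=1)
                    for ax in range(3)
                ],
                axis=1,
            )
            vec[~ok] = fallback
    signed = np.einsum("ij,ij->i", vec, surface.vertex_normals)
    m = EFSurfaceMap(
        stimulus_id=stimulus_id,
        vectors=vec,
        ef_strength=np.linalg.norm(vec, axis=1),
        ef_normal=np.abs(signed),
        ef_normal_signed=signed,
        intensity_pct_mso=ef.intensity_pct_mso,
    )
    m.validate()
    return m


def write_surface_map(m: EFSurfaceMap, path: str | Path) -> None:
    pd.DataFrame(
        {
            "vertex_id": np.arange(m.n_vertices),
            "Ex": m.vectors[:, 0],
            "Ey": m.vectors[:, 1],
            "Ez": m.vectors[:, 2],
            "strength": m.ef_strength,
            "normal": m.ef_normal,
        }
    ).to_csv(path, index=False)


def read_surface_map(
    path: str | Path, stimulus_id: str = "", intensity_pct_mso: float = 100.0
) -> EFSurfaceMap:
    df = pd.read_csv(path)
    vec = df[["Ex", "Ey", "Ez"]].to_numpy()
    return EFSurfaceMap(
        stimulus_id=stimulus_id,
        vectors=vec,
        ef_strength=df["strength"].to_numpy(),
        ef_normal=df["normal"].to_numpy(),
        ef_normal_signed=df["normal"].to_numpy(),
        intensity_pct_mso=intensity_pct_mso,
    )
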