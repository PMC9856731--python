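"""Multiplicative hotspot localization on the cortical surface.

The cortical representation of a muscle is localized by multiplying,
vertex-wise, the EF maps of the stimuli that elicited the largest
motor-evoked potentials:

    EF_focal(v) = prod_i EF_i(v),

with each factor normalized to unit maximum and the product accumulated
in the log domain for numerical safety.  The hotspot is the region where
the (re-normalized) product exceeds 10% of its maximum; its area and
intensity-weighted center of gravity (CoG) summarize the representation,
and Euclidean CoG distances compare muscles or subjects.  Because the
threshold is relative, the mask, area and CoG are invariant to positive
rescaling of any input map — only the spatial pattern of the fields
matters, not their absolute amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .head import CorticalSurface
from .surface_metrics import EFSurfaceMap

__all__ = [
    "HotspotMap",
    "select_top_stimuli",
    "multiply_maps",
    "center_of_gravity",
    "cog_distance",
    "group_hotspot",
]

RECORD_COLUMNS = ["placement_id", "trial", "muscle", "mep_pp", "intensity_pct_mso"]

_LOG_FLOOR = 1e-12


@dataclass
class HotspotMap:
    """Normalized product map with suprathreshold mask, area and CoG."""

    muscle: str
    metric: str                      # "strength" or "normal"
    k_samples: int
    ef_focal: np.ndarray             # per-vertex, max = 1
    mask: np.ndarray                 # ef_focal > threshold
    area_mm2: float
    cog: np.ndarray                  # world mm
    threshold: float = 0.1
    stimulus_ids: tuple[str, ...] = ()

    def validate(self) -> None:
        if not np.isclose(self.ef_focal.max(), 1.0):
            raise ValueError("ef_focal must be normalized to unit maximum")
        if not np.array_equal(self.mask, self.ef_focal > self.threshold):
            raise ValueError("mask inconsistent with the relative threshold")
        if self.mask.any() and not self.area_mm2 > 0:
            raise ValueError("suprathreshold vertices exist but area is zero")


def select_top_stimuli(
    records: pd.DataFrame,
    muscle: str,
    k: int,
    intensity_pct_mso: float | None = None,
    reduce: str = "median",
) -> list[str]:
    """Placements of the ``k`` largest MEP responses for one muscle.

    The (typically five) trials of each placement are first reduced to a
    single value (``"median"`` by default, ``"max"`` optionally;
    ``"trial"`` selects on raw trials and deduplicates by placement).
    Ties are broken by placement id so the selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = records[records["muscle"] == muscle]
    if intensity_pct_mso is not None:
        df = df[df["intensity_pct_mso"] == intensity_pct_mso]
    if df.empty:
        raise ValueError(f"no records for muscle {muscle!r}")

    if reduce in ("median", "max"):
        per = df.groupby("placement_id")["mep_pp"].agg(reduce)
        per = per.sort_index().sort_values(ascending=False, kind="stable")
        ids = list(per.index)
    elif reduce == "trial":
        df = df.sort_values(
            ["mep_pp", "placement_id"], ascending=[False, True], kind="stable"
        )
        ids = list(dict.fromkeys(df["placement_id"]))
    else:
        raise ValueError(f"unknown reduction {reduce!r}")

    if k > len(ids):
        raise ValueError(
            f"k={k} exceeds the {len(ids)} distinct placements available"
        )
    return ids[:k]


def multiply_maps(
    maps: list[EFSurfaceMap],
    metric: str,
    surface: CorticalSurface,
    muscle: str = "",
    threshold: float = 0.1,
) -> HotspotMap:
    """Vertex-wise product of EF maps, thresholded at 10% of its maximum.

    Each map is normalized to unit maximum before multiplication (the
    relative threshold makes the mask independent of this choice; the CoG
    weighting is mildly affected, see the package methods note).  A
    triangle contributes its full area when the mean of its three vertex
    values is suprathreshold.
    """
    if not maps:
        raise ValueError("need at least one EF map")
    n_v = maps[0].n_vertices
    if any(m.n_vertices != n_v for m in maps) or surface.n_vertices != n_v:
        raise ValueError("EF maps / surface have mismatched vertex counts")

    log_sum = np.zeros(n_v)
    for m in maps:
        v = m.metric(metric)
        vmax = v.max()
        if vmax <= 0:
            raise ValueError(f"map {m.stimulus_id!r} has non-positive maximum")
        log_sum += np.log(np.maximum(v / vmax, _LOG_FLOOR))
    ef_focal = np.exp(log_sum - log_sum.max())  # re-normalized to max 1

    mask = ef_focal > threshold
    tri_vals = ef_focal[surface.triangles].mean(axis=1)
    area = float(surface.triangle_areas()[tri_vals > threshold].sum())

    hmap = HotspotMap(
        muscle=muscle,
        metric=metric,
        k_samples=len(maps),
        ef_focal=ef_focal,
        mask=mask,
        area_mm2=area,
        cog=np.full(3, np.nan),
        threshold=threshold,
        stimulus_ids=tuple(m.stimulus_id for m in maps),
    )
    hmap.cog = center_of_gravity(hmap, surface)
    return hmap


def center_of_gravity(
    hmap: HotspotMap, surface: CorticalSurface, weighting: str = "focal"
) -> np.ndarray:
    """Weighted centroid of the suprathreshold region (world mm).

    Weights are ``ef_focal * vertex_area`` (``weighting="focal"``) or the
    bare vertex areas (``weighting="binary"``).
    """
    if not hmap.mask.any():
        raise ValueError("hotspot mask is empty; no center of gravity")
    idx = np.flatnonzero(hmap.mask)
    w = surface.vertex_area_mm2[idx]
    if weighting == "focal":
        w = w * hmap.ef_focal[idx]
    elif weighting != "binary":
        raise ValueError(f"unknown weighting {weighting!r}")
    return (w[:, None] * surface.vertices[idx]).sum(0) / w.sum()


def cog_distance(map_a: HotspotMap, map_b: HotspotMap) -> float:
    """Euclidean distance (mm) between two hotspot centers of gravity."""
    return float(np.linalg.norm(np.asarray(map_a.cog) - np.asarray(map_b.cog)))


def group_hotspot(maps: list[HotspotMap]) -> np.ndarray:
    """Vertex-wise sum of unit-max individual maps on a shared topology.

    Synthetic subjects are generated from a common template, so identity
    vertex correspondence replaces nonlinear template registration.
    """
    if not maps:
        raise ValueError("need at least one hotspot map")
    n_v = maps[0].ef_focal.size
    if any(m.ef_focal.size != n_v for m in maps):
        raise ValueError("hotspot maps have mismatched vertex counts (topology)")
    out = np.zeros(n_v)
    for m in maps:
        out += m.ef_focal / m.ef_focal.max()
    return out
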