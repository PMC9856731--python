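"""Multiplicative hotspot localization: selection, product algebra, CoG."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tmsmap.hotspot import (
    HotspotMap,
    center_of_gravity,
    cog_distance,
    group_hotspot,
    multiply_maps,
    select_top_stimuli,
)
from tmsmap.surface_metrics import EFSurfaceMap


def records_from(meps: dict[str, float], muscle="FDI", pct=55.0) -> pd.DataFrame:
    rows = [(pid, 0, muscle, v, pct) for pid, v in meps.items()]
    return pd.DataFrame(
        rows, columns=["placement_id", "trial", "muscle", "mep_pp", "intensity_pct_mso"]
    )


def fake_map(values, normals=None, stimulus_id="m") -> EFSurfaceMap:
    v = np.asarray(values, float)
    vec = np.zeros((v.size, 3))
    vec[:, 0] = v
    return EFSurfaceMap(
        stimulus_id=stimulus_id,
        vectors=vec,
        ef_strength=np.abs(v),
        ef_normal=np.abs(v),
        ef_normal_signed=v,
        intensity_pct_mso=55.0,
    )


class TestSelection:
    def test_largest_mep_wins(self):
        recs = records_from({"A": 2.0, "B": 1.0})
        assert select_top_stimuli(recs, "FDI", 1) == ["A"]

    def test_five_distinct_from_protocol(self, records_noisy):
        ids = select_top_stimuli(records_noisy, "FDI", 5, intensity_pct_mso=55.0)
        assert len(ids) == 5 and len(set(ids)) == 5

    def test_tie_break_by_placement_id(self):
        recs = records_from({"c": 1.0, "a": 1.0, "b": 1.0})
        assert select_top_stimuli(recs, "FDI", 2) == ["a", "b"]

    def test_k_exceeding_placements_raises(self):
        recs = records_from({"A": 2.0, "B": 1.0})
        with pytest.raises(ValueError, match="exceeds"):
            select_top_stimuli(recs, "FDI", 3)

    def test_median_reduction_over_trials(self):
        rows = [("A", t, "FDI", v, 55.0) for t, v in enumerate([0.1, 0.1, 0.1, 9, 9])]
        rows += [("B", t, "FDI", 0.5, 55.0) for t in range(5)]
        recs = pd.DataFrame(
            rows,
            columns=["placement_id", "trial", "muscle", "mep_pp", "intensity_pct_mso"],
        )
        # median(A)=0.1 < median(B)=0.5, but max(A)=9 > max(B)
        assert select_top_stimuli(recs, "FDI", 1, reduce="median") == ["B"]
        assert select_top_stimuli(recs, "FDI", 1, reduce="max") == ["A"]


class TestProduct:
    def test_single_map_identity(self, flat_patch):
        vals = np.linspace(0.01, 1.0, flat_patch.n_vertices)
        h = multiply_maps([fake_map(vals)], "strength", flat_patch)
        assert np.array_equal(h.mask, vals / vals.max() > 0.1)
        assert np.allclose(h.ef_focal, vals / vals.max())

    def test_permutation_invariance(self, flat_patch):
        rng = np.random.default_rng(0)
        maps = [
            fake_map(rng.uniform(0.01, 1.0, flat_patch.n_vertices), stimulus_id=str(i))
            for i in range(4)
        ]
        h1 = multiply_maps(maps, "strength", flat_patch)
        h2 = multiply_maps(maps[::-1], "strength", flat_patch)
        assert np.allclose(h1.ef_focal, h2.ef_focal)
        assert np.array_equal(h1.mask, h2.mask)
        assert h1.area_mm2 == h2.area_mm2
        assert np.allclose(h1.cog, h2.cog)

    def test_positive_scaling_invariance(self, flat_patch):
        rng = np.random.default_rng(1)
        vals = [rng.uniform(0.01, 1.0, flat_patch.n_vertices) for _ in range(3)]
        h1 = multiply_maps([fake_map(v) for v in vals], "strength", flat_patch)
        h2 = multiply_maps(
            [fake_map(v * s) for v, s in zip(vals, (7.0, 0.003, 120.0))],
            "strength",
            flat_patch,
        )
        assert np.array_equal(h1.mask, h2.mask)
        assert np.isclose(h1.area_mm2, h2.area_mm2)
        assert np.allclose(h1.cog, h2.cog)

    def test_duplicated_map_sharpens(self, flat_patch):
        """Threshold algebra: thresholding f^2 at 0.1 max is f > sqrt(0.1) max."""
        rng = np.random.default_rng(2)
        f = rng.uniform(0.01, 1.0, flat_patch.n_vertices)
        h1 = multiply_maps([fake_map(f)], "strength", flat_patch)
        h2 = multiply_maps([fake_map(f), fake_map(f)], "strength", flat_patch)
        assert np.all(h2.mask <= h1.mask)  # nested
        assert h2.area_mm2 <= h1.area_mm2
        assert np.array_equal(h2.mask, f > np.sqrt(0.1) * f.max())

    def test_mask_matches_relative_threshold_definition(self, flat_patch):
        rng = np.random.default_rng(3)
        maps = [
            fake_map(rng.uniform(0.01, 1.0, flat_patch.n_vertices)) for _ in range(3)
        ]
        h = multiply_maps(maps, "strength", flat_patch)
        h.validate()
        assert np.array_equal(h.mask, h.ef_focal > 0.1 * h.ef_focal.max())

    def test_mismatched_vertex_counts_raise(self, flat_patch):
        with pytest.raises(ValueError, match="mismatch"):
            multiply_maps(
                [fake_map(np.ones(flat_patch.n_vertices)), fake_map(np.ones(4))],
                "strength",
                flat_patch,
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            (3, 36),
            elements=st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False),
        )
    )
    def test_product_properties_hold_for_arbitrary_positive_maps(
        self, flat_patch, values
    ):
        maps = [fake_map(values[i], stimulus_id=str(i)) for i in range(3)]
        h = multiply_maps(maps, "strength", flat_patch)
        assert np.isclose(h.ef_focal.max(), 1.0)
        assert np.all((h.ef_focal >= 0) & (h.ef_focal <= 1.0 + 1e-12))
        hp = multiply_maps(maps[::-1], "strength", flat_patch)
        assert np.allclose(h.ef_focal, hp.ef_focal)


class TestCenterOfGravity:
    def _patch_map(self, flat_patch, focal):
        focal = np.asarray(focal, float)
        return HotspotMap(
            muscle="FDI",
            metric="strength",
            k_samples=1,
            ef_focal=focal,
            mask=focal > 0.1 * focal.max(),
            area_mm2=1.0,
            cog=np.zeros(3),
        )

    def test_equal_weights_midpoint(self, flat_patch):
        focal = np.full(flat_patch.n_vertices, 1e-9)
        # two interior vertices with identical vertex areas, 2 mm apart in x
        ia = 1 * 6 + 2
        ib = 3 * 6 + 2
        focal[[ia, ib]] = 1.0
        cog = center_of_gravity(self._patch_map(flat_patch, focal), flat_patch)
        expected = 0.5 * (flat_patch.vertices[ia] + flat_patch.vertices[ib])
        assert np.allclose(cog, expected)

    def test_single_vertex(self, flat_patch):
        focal = np.full(flat_patch.n_vertices, 1e-9)
        focal[14] = 1.0
        cog = center_of_gravity(self._patch_map(flat_patch, focal), flat_patch)
        assert np.allclose(cog, flat_patch.vertices[14])

    def test_nine_to_one_weighting(self, flat_patch):
        focal = np.full(flat_patch.n_vertices, 1e-9)
        ia, ib = 1 * 6 + 2, 3 * 6 + 2  # same vertex areas
        focal[ia], focal[ib] = 0.9, 0.1
        cog = center_of_gravity(self._patch_map(flat_patch, focal), flat_patch)
        expected = 0.9 * flat_patch.vertices[ia] + 0.1 * flat_patch.vertices[ib]
        assert np.allclose(cog, expected)

    def test_empty_mask_raises(self, flat_patch):
        h = self._patch_map(flat_patch, np.ones(flat_patch.n_vertices))
        h.mask = np.zeros(flat_patch.n_vertices, bool)
        with pytest.raises(ValueError, match="empty"):
            center_of_gravity(h, flat_patch)

    def test_cog_distance_345(self, flat_patch):
        a = self._patch_map(flat_patch, np.ones(flat_patch.n_vertices))
        b = self._patch_map(flat_patch, np.ones(flat_patch.n_vertices))
        a.cog = np.array([0.0, 0.0, 0.0])
        b.cog = np.array([3.0, 4.0, 0.0])
        assert cog_distance(a, b) == 5.0
        assert cog_distance(a, a) == 0.0


class TestGroup:
    def _unit_map(self, focal):
        focal = np.asarray(focal, float)
        return HotspotMap(
            muscle="FDI", metric="strength", k_samples=1,
            ef_focal=focal, mask=focal > 0.1, area_mm2=1.0, cog=np.zeros(3),
        )

    def test_single_subject_identity(self):
        m = self._unit_map([0.2, 1.0, 0.5])
        assert np.allclose(group_hotspot([m]), m.ef_focal)

    def test_linear_in_identical_subjects(self):
        m = self._unit_map([0.2, 1.0, 0.5])
        assert np.allclose(group_hotspot([m, m, m]), 3.0 * m.ef_focal)

    def test_disjoint_single_vertex_hotspots(self):
        a = self._unit_map([1.0, 1e-12, 1e-12])
        b = self._unit_map([1e-12, 1e-12, 1.0])
        g = group_hotspot([a, b])
        assert np.isclose(g[0], 1.0) and np.isclose(g[2], 1.0)
        assert g[1] < 1e-9

    def test_topology_mismatch_raises(self):
        with pytest.raises(ValueError, match="topology"):
            group_hotspot([self._unit_map([1.0, 0.5]), self._unit_map([1.0])])
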