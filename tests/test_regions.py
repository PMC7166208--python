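"""Alias-location prediction and disk/control region masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smsleak as sl
from smsleak.errors import CoordinateError, ParameterError, PlacementError
from smsleak.geometry import AliasKind, VoxelCoord


def make_geom(n_pe=96, nz=68, mb=4, grappa=2, denom=3, pe_axis="y"):
    return sl.AcquisitionGeometry(
        nx=n_pe if pe_axis == "x" else 96,
        ny=n_pe if pe_axis == "y" else 96,
        nz=nz,
        mb_factor=mb,
        grappa_factor=grappa,
        caipi_denominator=denom,
        pe_axis=pe_axis,
    )


class TestPredictAliasLocations:
    def test_reference_source_mb4_grappa2(self):
        """Eye source (32, 91, 18) on the reference protocol: 8 locations,
        CAIPI and GRAPPA phase-encode coordinates per simultaneous slice."""
        locs = sl.predict_alias_locations(VoxelCoord(32, 91, 18), make_geom())
        assert len(locs) == 8
        caipi = {(l.slice_index, l.coord.y) for l in locs if l.kind is AliasKind.CAIPI}
        grappa = {(l.slice_index, l.coord.y) for l in locs if l.kind is AliasKind.GRAPPA}
        assert caipi == {(35, 27), (52, 59), (1, 91), (18, 27)}
        assert grappa == {(35, 75), (52, 11), (1, 43), (18, 75)}
        assert all(l.coord.x == 32 for l in locs)
        # cyclic slice order starting after the source slice; m=M is the source slice
        assert [(l.m, l.slice_index) for l in locs if l.kind is AliasKind.CAIPI] == [
            (1, 35), (2, 52), (3, 1), (4, 18)
        ]

    def test_mb1_single_in_plane_alias(self):
        locs = sl.predict_alias_locations(
            VoxelCoord(10, 20, 5), make_geom(mb=1, grappa=1)
        )
        assert len(locs) == 1
        (loc,) = locs
        assert tuple(loc.coord) == (10, 52, 5)
        assert loc.m == 1 and loc.kind is AliasKind.CAIPI

    def test_origin_source_mb4_no_grappa(self):
        locs = sl.predict_alias_locations(VoxelCoord(0, 0, 0), make_geom(grappa=1))
        assert [(l.coord.y, l.slice_index) for l in locs] == [
            (32, 17), (64, 34), (0, 51), (32, 0)
        ]

    def test_source_coincident_location_flagged_not_dropped(self):
        """With M equal to the CAIPI denominator, the m=M alias lands back
        on the source voxel and is flagged rather than removed."""
        gm = make_geom(n_pe=12, nz=12, mb=3, grappa=1, denom=3)
        locs = sl.predict_alias_locations(VoxelCoord(5, 7, 4), gm)
        assert len(locs) == 3
        coincident = [l for l in locs if l.is_source_coincident]
        assert len(coincident) == 1
        assert tuple(coincident[0].coord) == (5, 7, 4)
        assert coincident[0].m == 3

    def test_source_outside_grid_rejected(self):
        with pytest.raises(CoordinateError):
            sl.predict_alias_locations(VoxelCoord(96, 0, 0), make_geom())

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(
        mb=st.integers(1, 4),
        grappa=st.sampled_from([1, 2]),
        sx=st.integers(0, 11),
        sy=st.integers(0, 11),
        sz=st.integers(0, 11),
    )
    def test_location_count_invariant(self, mb, grappa, sx, sy, sz):
        """|locations| = M when R = 1, 2M when R > 1."""
        gm = make_geom(n_pe=12, nz=12, mb=mb, grappa=grappa)
        locs = sl.predict_alias_locations(VoxelCoord(sx, sy, sz), gm)
        assert len(locs) == mb * (2 if grappa > 1 else 1)
        assert all(0 <= l.coord.y < 12 for l in locs)
        assert all(l.coord.z == l.slice_index for l in locs)

    def test_pe_axis_swap_moves_shift_to_other_axis(self):
        """Left-right phase encoding shifts x instead of y (lateral aliases)."""
        src = VoxelCoord(40, 40, 18)
        locs_y = sl.predict_alias_locations(src, make_geom(pe_axis="y"))
        locs_x = sl.predict_alias_locations(src, make_geom(pe_axis="x"))
        swapped = {(l.coord.y, l.coord.x, l.coord.z, l.kind, l.m) for l in locs_x}
        original = {(l.coord.x, l.coord.y, l.coord.z, l.kind, l.m) for l in locs_y}
        assert swapped == original

    @pytest.mark.parametrize("n_pe", [12, 24])
    @pytest.mark.parametrize("mb", [2, 3, 4])
    @pytest.mark.parametrize("grappa", [1, 2])
    def test_matches_exhaustive_enumeration(self, n_pe, mb, grappa):
        """Predicted alias sets equal a brute-force enumeration that walks
        the CAIPI shift by repeated addition over every simultaneous slice."""
        gm = make_geom(n_pe=n_pe, nz=12, mb=mb, grappa=grappa)
        src = VoxelCoord(3, n_pe - 2, 7)
        expected = set()
        stride = 12 // mb
        group = [z for z in range(12) if z % stride == 7 % stride]
        after = sorted(z for z in group if z > 7) + sorted(z for z in group if z <= 7)
        base = round(n_pe / 3)
        for m, z in enumerate(after, start=1):
            pos = src.y
            for _ in range(m):
                pos += base
                if pos >= n_pe:
                    pos -= n_pe
            expected.add((src.x, pos, z, "caipi", m))
            if grappa > 1:
                ghost = pos + n_pe // 2
                if ghost >= n_pe:
                    ghost -= n_pe
                expected.add((src.x, ghost, z, "grappa", m))
        got = {
            (l.coord.x, l.coord.y, l.coord.z, l.kind.value, l.m)
            for l in sl.predict_alias_locations(src, gm)
        }
        assert got == expected


class TestDiskMask:
    @pytest.mark.parametrize("diameter,count", [(7, 29), (5, 13), (1, 1), (3, 5)])
    def test_interior_disk_cardinality(self, diameter, count):
        mask = sl.disk_mask(VoxelCoord(40, 40, 10), diameter, make_geom())
        assert mask.n_voxels == count
        assert all(v.z == 10 for v in mask.voxels)

    def test_even_or_nonpositive_diameter_rejected(self):
        gm = make_geom()
        for bad in (0, -3, 6):
            with pytest.raises(ParameterError):
                sl.disk_mask(VoxelCoord(40, 40, 10), bad, gm)

    def test_edge_disk_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            mask = sl.disk_mask(VoxelCoord(0, 40, 10), 7, make_geom())
        assert mask.n_voxels < 29
        assert all(v.x >= 0 for v in mask.voxels)

    def test_disk_is_euclidean_ball_on_lattice(self):
        mask = sl.disk_mask(VoxelCoord(40, 40, 10), 7, make_geom())
        for v in mask.voxels:
            assert (v.x - 40) ** 2 + (v.y - 40) ** 2 <= 9


class TestControlMasks:
    def _setup(self):
        gm = make_geom(n_pe=48, nz=16, mb=4)
        brain = sl.head_phantom(gm)
        locs = sl.predict_alias_locations(VoxelCoord(24, 45, 9), gm)
        return gm, brain, locs

    def test_deterministic_given_seed(self):
        gm, brain, locs = self._setup()
        a = sl.control_masks(gm, locs, brain, n=2, min_distance=8, seed=11)
        b = sl.control_masks(gm, locs, brain, n=2, min_distance=8, seed=11)
        assert [m.center for m in a] == [m.center for m in b]

    def test_centers_in_brain_and_far_from_aliases(self):
        gm, brain, locs = self._setup()
        controls = sl.control_masks(gm, locs, brain, n=2, min_distance=8, seed=3)
        assert len(controls) == 2
        for c in controls:
            assert brain[c.center.x, c.center.y, c.center.z]
            for loc in locs:
                d = np.linalg.norm(np.subtract(tuple(c.center), tuple(loc.coord)))
                assert d >= 8
        # controls never overlap each other
        assert not (controls[0].voxels & controls[1].voxels)

    def test_unconstrained_placement_with_empty_alias_set(self):
        gm, brain, _ = self._setup()
        controls = sl.control_masks(gm, [], brain, n=3, min_distance=8, seed=5)
        assert len(controls) == 3

    def test_infeasible_distance_raises_placement_error(self):
        gm, brain, locs = self._setup()
        with pytest.raises(PlacementError):
            sl.control_masks(gm, locs, brain, n=2, min_distance=1000, seed=0)
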