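"""Predict where an eye-blink artefact will leak for the reference protocol.

With multiband factor 4 and GRAPPA 2, a signal source in one slice is
expected to alias into each of the 4 simultaneously excited slices at two
positions: the CAIPI FOV/3 shift and an additional FOV/2 GRAPPA ghost —
eight positions in total, all sharing the source's non-phase-encode
coordinate.
"""

import smsleak as sl

geom = sl.default_geometry()  # 96x96x68 grid, 2 mm voxels, MB4, GRAPPA 2, PE = y
source = sl.VoxelCoord(32, 91, 18)  # the eye, anterior and inferior

print(f"source voxel {tuple(source)}; simultaneous slices "
      f"{sl.slice_group(geom, source.z)}\n")
print(f"{'label':>6} {'class':>7} {'m':>2} {'x':>3} {'y':>3} {'slice':>5}")
for loc in sl.predict_alias_locations(source, geom):
    print(f"{sl.alias_label(loc):>6} {loc.kind.value:>7} {loc.m:>2} "
          f"{loc.coord.x:>3} {loc.coord.y:>3} {loc.slice_index:>5}"
          + ("  (source voxel itself)" if loc.is_source_coincident else ""))

mask = sl.disk_mask(sl.VoxelCoord(32, 27, 35), 7, geom)
print(f"\na diameter-7 quantification disk holds {mask.n_voxels} voxels")
print("Each row is one expected artefact position: signal from the eye "
      "reappears there after slice separation and in-plane unaliasing.")
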