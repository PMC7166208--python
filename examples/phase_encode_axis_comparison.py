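"""Compare alias placement for anterior-posterior vs left-right phase encoding.

Aliases propagate along the phase-encode axis.  For an anterior midline
source (the eyes), anterior-posterior encoding spreads aliases through
the head, while left-right encoding pushes them laterally — mostly into
the background outside a head that is narrower left-right than the field
of view.
"""

import warnings

import smsleak as sl

warnings.filterwarnings("ignore")
source = sl.VoxelCoord(24, 45, 9)

for axis, name in (("y", "anterior-posterior"), ("x", "left-right")):
    geom = sl.AcquisitionGeometry(48, 48, 16, voxel_size=(4.0,) * 3,
                                  mb_factor=4, grappa_factor=2, pe_axis=axis)
    head = sl.head_phantom(geom)
    ex, ey, ez = sl.disk_mask(source, 5, geom).indices()
    head[ex, ey, ez] = True  # the eye sits on the anterior head surface

    outside = 0
    total = 0
    for loc in sl.predict_alias_locations(source, geom):
        xs, ys, zs = sl.disk_mask(loc.coord, 7, geom).indices()
        outside += int((~head[xs, ys, zs]).sum())
        total += len(xs)
    print(f"PE {name:<19} ({axis}-axis): {outside:>3} of {total} "
          f"predicted alias voxels fall outside the head")

print("\nMore alias voxels outside the head means less eye-blink leakage "
      "contaminating brain tissue.")
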