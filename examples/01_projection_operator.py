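"""Build a beam's-eye-view projection operator and project a PTV.

Constructs the sparse voxel-to-beamlet matrix for the anterior beam of a
small isocenter-centered grid, projects a spherical target onto the
fluence plane, and dilates the footprint by the 5 mm clinical margin.
"""

import numpy as np

from dosefluence import (
    BeamGeometry,
    GridSpec,
    bev_target_mask,
    build_projection_operator,
    project_volume,
)

grid = GridSpec(shape=(16, 48, 48))  # 2.5 mm voxels, isocenter-centered
beam = BeamGeometry(fluence_shape=(32, 32))
op = build_projection_operator(grid, beam, beam_index=0)
print(f"beam 0 (gantry {op.angle_deg:.0f} deg): "
      f"{op.matrix.nnz} voxel->beamlet entries, "
      f"{op.n_truncated} voxels off-plane")

# spherical target at the isocenter
z, y, x = np.mgrid[0:16, 0:48, 0:48]
ptv = ((z - 7.5) ** 2 + (y - 23.5) ** 2 + (x - 23.5) ** 2) <= 4**2

footprint = project_volume(op, ptv.astype(float))
mask = bev_target_mask(ptv, op, margin_mm=5.0)
print(f"projected footprint: {int((footprint > 0).sum())} px; "
      f"with 5 mm margin: {int(mask.sum())} px")
# The footprint is the target's silhouette seen from the source through the
# isocenter plane; the margin adds a 2-pixel (5 mm) rim used by the
# fluence evaluation masks and the training loss.
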