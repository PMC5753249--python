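"""One-off generator for the bundled variable-domain reference core.

Writes src/tcrcurate/data/reference_core.txt: one line per framework IMGT
position, "pos x y z", expressed in the canonical frame (centroid at the
origin, principal axes aligned with x/y/z).  The point set is an idealised
two-layer beta-sandwich scaffold: two slightly twisted 4x4 grids 9 A apart.
Only the relative geometry matters; frames are defined by superposing this
core onto an observed domain.
"""

import numpy as np
from pathlib import Path

# 32 framework positions: sheet layer 1 (outer) and layer 2 (inner)
POSITIONS = [
    3, 4, 5, 6, 19, 20, 21, 22, 23, 24, 25, 26, 39, 40, 41, 42,
    66, 67, 68, 69, 70, 71, 89, 90, 91, 92, 101, 102, 103, 104, 118, 119,
]

pts = []
n = len(POSITIONS)
for i in range(n):
    layer = i % 2
    row, col = divmod(i // 2, 4)
    x = col * 6.0 + layer * 1.5
    y = row * 6.0
    z = layer * 9.0 + 0.35 * col * layer  # slight twist breaks symmetry
    pts.append((x, y, z))
pts = np.array(pts)

# canonicalise: centroid at origin, principal axes -> x/y/z with fixed signs
pts -= pts.mean(axis=0)
_, _, vt = np.linalg.svd(pts, full_matrices=False)
axes = vt.T
if np.linalg.det(axes) < 0:
    axes[:, 2] *= -1
pts = pts @ axes
for j in range(3):  # deterministic sign: first point has non-negative coords
    if pts[0, j] < 0:
        pts[:, j] *= -1
if np.linalg.det(np.eye(3)) < 0:  # pragma: no cover
    raise AssertionError

out = Path(__file__).resolve().parents[1] / "src" / "tcrcurate" / "data" / "reference_core.txt"
lines = ["# IMGT position, canonical-frame coordinates (A)"]
for pos, (x, y, z) in zip(POSITIONS, pts):
    lines.append(f"{pos} {x:.4f} {y:.4f} {z:.4f}")
out.write_text("\n".join(lines) + "\n")
print(f"wrote {out} ({len(POSITIONS)} positions)")
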