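"""Brute-force reference 3D thinning, used only as a test oracle.

Independent of the package's skeletonization path: sequential boundary
peeling that deletes a voxel only if it is a *simple point* (removal
preserves both foreground 26-connectivity and background 6-connectivity in
its 3x3x3 neighborhood, checked explicitly with component labeling) and
not a curve endpoint.  Slow but transparently correct on small masks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_S26 = np.ones((3, 3, 3), dtype=bool)
_S6 = ndimage.generate_binary_structure(3, 1)

# the 18-neighborhood: all offsets at Chebyshev distance 1 except corners
_N18 = np.ones((3, 3, 3), dtype=bool)
for _c in np.argwhere(np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0) == 3):
    _N18[tuple(_c)] = False
_N18[1, 1, 1] = False

_FACES = [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]


def _is_simple(nb: np.ndarray) -> bool:
    """Simple-point test on a 3x3x3 boolean neighborhood (center True)."""
    fg = nb.copy()
    fg[1, 1, 1] = False
    if not fg.any():
        return False  # isolated voxel: deleting changes topology
    lab, n = ndimage.label(fg, structure=_S26)
    if n != 1:
        return False
    bg = ~nb & _N18
    if not any(bg[f] for f in _FACES):
        return False  # interior voxel: not deletable
    lab_bg, _ = ndimage.label(bg, structure=_S6)
    face_comps = {lab_bg[f] for f in _FACES if bg[f]}
    return len(face_comps) == 1


def _is_endpoint(nb: np.ndarray) -> bool:
    fg = nb.copy()
    fg[1, 1, 1] = False
    return int(fg.sum()) <= 1


def reference_thinning(mask: np.ndarray) -> np.ndarray:
    """Thin a binary volume to a curve skeleton by sequential peeling."""
    mask = np.asarray(mask, bool)
    pad = np.pad(mask, 1)
    changed = True
    while changed:
        changed = False
        for axis, shift in (
            (0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)
        ):
            border = pad & ~np.roll(pad, shift, axis=axis)
            for v in np.argwhere(border):
                z, y, x = v
                if not pad[z, y, x]:
                    continue
                nb = pad[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2]
                if nb.shape != (3, 3, 3):
                    continue
                if _is_endpoint(nb):
                    continue
                if _is_simple(nb):
                    pad[z, y, x] = False
                    changed = True
    return pad[1:-1, 1:-1, 1:-1]
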