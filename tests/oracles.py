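"""Independent brute-force oracles used by the tests.

These deliberately avoid the implementation's code paths (scipy.ndimage
label/erosion, vectorized sums) so they can serve as ground truth.
"""

from collections import deque

import numpy as np


def brute_erode_6(mask: np.ndarray) -> np.ndarray:
    """One 6-neighbor erosion step by explicit neighbor checks."""
    nx, ny, nz = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                keep = True
                for dx, dy, dz in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
                ):
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                        keep = False  # volume boundary counts as outside
                        break
                    if not mask[xx, yy, zz]:
                        keep = False
                        break
                out[x, y, z] = keep
    return out


_NEIGH6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _components(supra: np.ndarray) -> np.ndarray:
    """Connected-component sizes by breadth-first flood fill (6-connectivity).

    Returns an array of the component size at each suprathreshold voxel
    (0 elsewhere).
    """
    shape = supra.shape
    comp = -np.ones(shape, dtype=int)
    sizes = []
    for start in zip(*np.nonzero(supra)):
        if comp[start] >= 0:
            continue
        cid = len(sizes)
        queue = deque([start])
        comp[start] = cid
        count = 0
        while queue:
            x, y, z = queue.popleft()
            count += 1
            for dx, dy, dz in _NEIGH6:
                xx, yy, zz = x + dx, y + dy, z + dz
                if (
                    0 <= xx < shape[0]
                    and 0 <= yy < shape[1]
                    and 0 <= zz < shape[2]
                    and supra[xx, yy, zz]
                    and comp[xx, yy, zz] < 0
                ):
                    comp[xx, yy, zz] = cid
                    queue.append((xx, yy, zz))
        sizes.append(count)
    size_map = np.zeros(shape)
    for cid, n in enumerate(sizes):
        size_map[comp == cid] = n
    return size_map


def brute_tfce(stat_map: np.ndarray, E: float = 0.5, H: float = 2.0,
               n_steps: int = 100, dh: float | None = None) -> np.ndarray:
    """Per-threshold component labeling and explicit summation."""
    values = np.asarray(stat_map, dtype=float)
    peak = float(values.max(initial=0.0))
    out = np.zeros(values.shape)
    if peak <= 0:
        return out
    step = peak / n_steps if dh is None else dh
    n_rungs = int(np.floor(peak / step * (1 + 1e-9)))
    for i in range(1, n_rungs + 1):
        h = i * step
        supra = values >= h
        size_map = _components(supra)
        out += np.where(supra, size_map**E * h**H * step, 0.0)
    return out
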