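"""Independent brute-force oracles shared by the test modules."""

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling, independent of scipy.ndimage."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dz) + abs(dy) + abs(dx) != 1:
                    continue
                offsets.append((dz, dy, dx))
    out = np.zeros(mask.shape, dtype=int)
    nid = 0
    for idx in zip(*np.nonzero(mask)):
        if out[idx]:
            continue
        nid += 1
        q = deque([idx])
        out[idx] = nid
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (0 <= n[0] < mask.shape[0] and 0 <= n[1] < mask.shape[1]
                        and 0 <= n[2] < mask.shape[2]
                        and mask[n] and not out[n]):
                    out[n] = nid
                    q.append(n)
    return out


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label maps induce the same partition of the foreground."""
    fg = a > 0
    if not np.array_equal(fg, b > 0):
        return False
    pairs = set(zip(a[fg].ravel(), b[fg].ravel()))
    return (len({p[0] for p in pairs}) == len(pairs)
            and len({p[1] for p in pairs}) == len(pairs))
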