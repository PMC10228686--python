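"""Independent brute-force oracles used to cross-check the implementation."""

from collections import deque

import numpy as np


def bfs_component_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Connected-component count by breadth-first search (queue-based)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask)
    count = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        count += 1
        q = deque([(sy, sx)])
        seen[sy, sx] = True
        while q:
            y, x = q.popleft()
            for dy, dx in neigh:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                    seen[ny, nx] = True
                    q.append((ny, nx))
    return count


def otsu_exhaustive(img: np.ndarray) -> float:
    """Threshold maximizing between-class variance by exhaustive search."""
    v = np.sort(np.unique(np.asarray(img, float)))
    best_t, best_var = v[0], -1.0
    for t in (v[:-1] + v[1:]) / 2.0:
        lo, hi = img[img <= t], img[img > t]
        w0, w1 = lo.size / img.size, hi.size / img.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def threshold_rule_oracle(responses: dict[float, int]) -> float:
    """Exhaustive evaluation of the >=3-of-6 sensitivity threshold rule."""
    best = 0.0
    for length, positives in responses.items():
        if positives >= 3 and length > best:
            best = length
    return best
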