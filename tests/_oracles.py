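"""Independent brute-force oracles for texture-matrix construction.

Everything here is written as plain nested loops over voxels, runs and zones
— deliberately naive and independent of the vectorized implementations it
cross-checks.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def glcm_pairs(labels: np.ndarray, direction: tuple[int, int, int], ng: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair counting."""
    counts = np.zeros((ng, ng))
    nx, ny, nz = labels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = labels[x, y, z]
                if a == 0:
                    continue
                u, v, w = x + direction[0], y + direction[1], z + direction[2]
                if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz):
                    continue
                b = labels[u, v, w]
                if b == 0:
                    continue
                counts[a - 1, b - 1] += 1
    sym = counts + counts.T
    total = sym.sum()
    return sym / total if total > 0 else sym


def glrlm_runs(labels: np.ndarray, direction: tuple[int, int, int], ng: int) -> np.ndarray:
    """Run-length matrix by explicitly walking every lattice line."""
    nx, ny, nz = labels.shape
    runs: list[tuple[int, int]] = []

    def inside(p):
        return 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                prev = (x - direction[0], y - direction[1], z - direction[2])
                a = labels[x, y, z]
                if a == 0:
                    continue
                # only start a run at the beginning of a same-label segment
                if inside(prev) and labels[prev] == a:
                    continue
                length = 1
                cur = (x + direction[0], y + direction[1], z + direction[2])
                while inside(cur) and labels[cur] == a:
                    length += 1
                    cur = (cur[0] + direction[0], cur[1] + direction[1], cur[2] + direction[2])
                runs.append((a, length))

    max_len = max((l for _, l in runs), default=1)
    mat = np.zeros((ng, max_len))
    for level, length in runs:
        mat[level - 1, length - 1] += 1
    return mat


def glszm_zones(labels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix by flood fill over 26-connected equal-label zones."""
    visited = np.zeros(labels.shape, dtype=bool)
    nx, ny, nz = labels.shape
    zones: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if labels[x, y, z] == 0 or visited[x, y, z]:
                    continue
                level = labels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        nxt = (cx + dx, cy + dy, cz + dz)
                        if (
                            0 <= nxt[0] < nx
                            and 0 <= nxt[1] < ny
                            and 0 <= nxt[2] < nz
                            and not visited[nxt]
                            and labels[nxt] == level
                        ):
                            visited[nxt] = True
                            stack.append(nxt)
                zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, max_size))
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat


def gldm_table(labels: np.ndarray, ng: int) -> np.ndarray:
    """Dependence matrix by explicit neighbor counting (alpha = 0)."""
    nx, ny, nz = labels.shape
    entries: list[tuple[int, int]] = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = labels[x, y, z]
                if a == 0:
                    continue
                dep = 0
                for dx, dy, dz in NEIGHBORS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and labels[u, v, w] == a:
                        dep += 1
                entries.append((a, dep + 1))
    max_dep = max((d for _, d in entries), default=1)
    mat = np.zeros((ng, max_dep))
    for level, dep in entries:
        mat[level - 1, dep - 1] += 1
    return mat


def ngtdm_ns(labels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i, n_valid) by explicit neighborhood averaging."""
    nx, ny, nz = labels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    nvalid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = labels[x, y, z]
                if a == 0:
                    continue
                nb = []
                for dx, dy, dz in NEIGHBORS_26:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and labels[u, v, w] > 0:
                        nb.append(labels[u, v, w])
                if not nb:
                    continue
                nvalid += 1
                n[a - 1] += 1
                s[a - 1] += abs(a - float(np.mean(nb)))
    return n, s, nvalid
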