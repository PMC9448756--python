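"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive loops, closed forms,
direct enumeration) and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# prominence-filtered maxima: literal path/flood-fill definition
# ---------------------------------------------------------------------------

def _neighbors8(i: int, j: int, shape) -> list[tuple[int, int]]:
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < shape[0] and 0 <= b < shape[1]:
                out.append((a, b))
    return out


def _plateaus(img: np.ndarray) -> list[list[tuple[int, int]]]:
    """Connected equal-valued components with no strictly higher 8-neighbour."""
    shape = img.shape
    seen = np.zeros(shape, dtype=bool)
    plateaus = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            if seen[i, j]:
                continue
            v = img[i, j]
            comp = []
            is_max = True
            q = deque([(i, j)])
            seen[i, j] = True
            while q:
                p = q.popleft()
                comp.append(p)
                for nb in _neighbors8(*p, shape):
                    if img[nb] > v:
                        is_max = False
                    if img[nb] == v and not seen[nb]:
                        seen[nb] = True
                        q.append(nb)
            if is_max and len(comp) < img.size:
                plateaus.append(comp)
    return plateaus


def prominence_maxima_oracle(img: np.ndarray, prominence: float) -> set[tuple[int, int]]:
    """Exhaustive flood-fill version of the prominence maxima rule.

    A plateau of height v is suppressed iff some pixel > v is reachable
    through pixels >= v - prominence.  Surviving plateaus of equal height
    that are mutually reachable through pixels >= v - prominence merge into
    a single point (centroid of the merged plateaus, half rounded down).
    """
    img = np.asarray(img, dtype=np.float64)
    shape = img.shape
    if img.size == 0 or img.min() == img.max():
        return set()

    survivors: list[tuple[float, list[tuple[int, int]], frozenset]] = []
    for comp in _plateaus(img):
        v = img[comp[0]]
        # flood over pixels >= v - prominence starting from the plateau
        thr = v - prominence
        seen = set(comp)
        q = deque(comp)
        suppressed = False
        while q:
            p = q.popleft()
            for nb in _neighbors8(*p, shape):
                if img[nb] >= thr and nb not in seen:
                    if img[nb] > v:
                        suppressed = True
                    seen.add(nb)
                    q.append(nb)
        if not suppressed:
            survivors.append((v, comp, frozenset(seen)))

    # merge tied survivors whose tolerance floods touch each other's plateau
    points: set[tuple[int, int]] = set()
    used = [False] * len(survivors)
    for a in range(len(survivors)):
        if used[a]:
            continue
        v, comp, flood = survivors[a]
        group = list(comp)
        used[a] = True
        changed = True
        while changed:
            changed = False
            for b in range(len(survivors)):
                if used[b] or survivors[b][0] != v:
                    continue
                if any(p in flood for p in survivors[b][1]):
                    group.extend(survivors[b][1])
                    flood = flood | survivors[b][2]
                    used[b] = True
                    changed = True
        arr = np.array(group, dtype=float)
        m = arr.mean(axis=0)
        points.add(tuple(int(np.ceil(c - 0.5)) for c in m))
    return points


# ---------------------------------------------------------------------------
# surface model: literal 6-neighbour check
# ---------------------------------------------------------------------------

def surface_voxels_oracle(volume: np.ndarray) -> np.ndarray:
    vol = np.asarray(volume, dtype=bool)
    out = np.zeros_like(vol)
    nx, ny, nz = vol.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not vol[x, y, z]:
                    continue
                for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    a, b, c = x + dx, y + dy, z + dz
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and not vol[a, b, c]:
                        out[x, y, z] = True
                        break
    return out


# ---------------------------------------------------------------------------
# rank statistics by hand
# ---------------------------------------------------------------------------

def midranks(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of midranks, computed from first principles."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def ranksum_exact_oracle(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every rank assignment."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = len(a)
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    w = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2.0
    obs = abs(w - mean)
    hits = total = 0
    for subset in combinations(range(len(pooled)), na):
        total += 1
        if abs(sum(ranks[k] for k in subset) - mean) >= obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# analytic Frangi response of Gaussian-profile structures
# ---------------------------------------------------------------------------

def gaussian_tube_center_eigs(a: float, sigma: float) -> tuple[float, float, float]:
    """sigma^2-normalized Hessian eigenvalues at the axis of a Gaussian tube
    of profile exp(-r^2 / 2 a^2) after smoothing with a Gaussian of width
    sigma (both in the same physical units)."""
    s2 = a * a + sigma * sigma
    amp = a * a / s2  # 2D convolution amplitude
    lam_perp = -sigma * sigma * amp / s2
    return 0.0, lam_perp, lam_perp


def gaussian_blob_center_eigs(a: float, sigma: float) -> tuple[float, float, float]:
    s2 = a * a + sigma * sigma
    amp = (a * a / s2) ** 1.5  # 3D convolution amplitude
    lam = -sigma * sigma * amp / s2
    return lam, lam, lam


def frangi_from_eigs(l1, l2, l3, alpha=0.5, beta=0.5, c=None, smax=None):
    """Frangi response from given (|l1|<=|l2|<=|l3|) eigenvalues."""
    if l2 > 0 or l3 > 0:
        return 0.0
    eps = 1e-10
    Ra = abs(l2) / (abs(l3) + eps)
    Rb = abs(l1) / (np.sqrt(abs(l2) * abs(l3)) + eps)
    S = np.sqrt(l1 * l1 + l2 * l2 + l3 * l3)
    if c is None:
        c = 0.5 * (smax if smax is not None else S)
    return float(
        (1 - np.exp(-(Ra**2) / (2 * alpha**2)))
        * np.exp(-(Rb**2) / (2 * beta**2))
        * (1 - np.exp(-(S**2) / (2 * c**2)))
    )
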