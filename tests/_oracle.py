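"""Brute-force greedy region-merging oracle, independent of the package
implementation: objects are kept as explicit pixel sets and every pair cost
is recomputed from scratch at every step.

Shares the cost *definition* (that is the point of the check) but none of
the incremental bookkeeping: statistics come from numpy over raw pixel
lists, adjacency is rediscovered each round, and the same deterministic
tie-breaking is applied (minimal (cost, low id, high id); the merged object
keeps the id of the larger part, lower id on ties).
"""

from __future__ import annotations

import numpy as np


def _perimeter(pixels: set[tuple[int, int]]) -> int:
    per = 0
    for r, c in pixels:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in pixels:
                per += 1
    return per


def _object_stats(stack: np.ndarray, pixels: set[tuple[int, int]]):
    rr = [p[0] for p in pixels]
    cc = [p[1] for p in pixels]
    vals = stack[:, rr, cc]  # (L, n)
    n = len(pixels)
    sds = vals.std(axis=1)
    per = _perimeter(pixels)
    h = max(rr) - min(rr) + 1
    w = max(cc) - min(cc) + 1
    return n, sds, per, h, w


def _merge_cost(stack, weights, shape_factor, compactness, pa, pb):
    na, sda, la, ha, wa = _object_stats(stack, pa)
    nb, sdb, lb, hb, wb = _object_stats(stack, pb)
    union = pa | pb
    nc, sdc, lc, hc, wc = _object_stats(stack, union)
    dcolor = float(np.sum(weights * (nc * sdc - na * sda - nb * sdb)))
    if shape_factor == 0.0:
        return dcolor
    dcmpct = lc * np.sqrt(nc) - la * np.sqrt(na) - lb * np.sqrt(nb)
    dsmooth = (
        nc * lc / (2.0 * (hc + wc))
        - na * la / (2.0 * (ha + wa))
        - nb * lb / (2.0 * (hb + wb))
    )
    return (1.0 - shape_factor) * dcolor + shape_factor * (
        compactness * dcmpct + (1.0 - compactness) * dsmooth
    )


def _adjacent(pa, pb) -> bool:
    for r, c in pa:
        if ((r + 1, c) in pb or (r - 1, c) in pb or (r, c + 1) in pb or (r, c - 1) in pb):
            return True
    return False


def oracle_segment(stack: np.ndarray, scale: float, shape_factor: float = 0.2,
                   compactness: float = 0.6,
                   band_weights=None) -> np.ndarray:
    """Label raster from exhaustive greedy merging; threshold is scale**2."""
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    L, rows, cols = stack.shape
    if band_weights is None:
        band_weights = [1.0] * L
        if L >= 4:
            band_weights[3] = 2.0
    weights = np.asarray(band_weights, float)
    weights = weights / weights.sum()

    objects: dict[int, set[tuple[int, int]]] = {
        r * cols + c: {(r, c)} for r in range(rows) for c in range(cols)
    }
    threshold = scale * scale
    while len(objects) > 1:
        best = None
        ids = sorted(objects)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if not _adjacent(objects[a], objects[b]):
                    continue
                cost = _merge_cost(
                    stack, weights, shape_factor, compactness, objects[a], objects[b]
                )
                key = (cost, a, b)
                if best is None or key < best:
                    best = key
        if best is None or best[0] >= threshold:
            break
        _, a, b = best
        # merged object keeps the id of the larger part (lower id on ties)
        if len(objects[b]) > len(objects[a]) or (
            len(objects[b]) == len(objects[a]) and b < a
        ):
            a, b = b, a
        objects[a] = objects[a] | objects[b]
        del objects[b]

    labels = np.zeros((rows, cols), dtype=int)
    for oid, pixels in objects.items():
        for r, c in pixels:
            labels[r, c] = oid
    return labels


def canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel a partition into first-appearance order for comparison."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, v in enumerate(labels.ravel()):
        out.ravel()[i] = mapping.setdefault(int(v), len(mapping))
    return out
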