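"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's implementation paths: the
maxima oracle floods per candidate with a pure-Python BFS, and the Otsu
oracle loops over every candidate threshold with the textbook
between-class-variance formula.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest


def oracle_find_maxima(image, tol, mask=None):
    """Exhaustive prominence/flood oracle for find_maxima.

    For every regional-maximum plateau of value v, flood over pixels with
    value strictly greater than ``v - tol`` (8-connected, within the mask).
    The candidate is suppressed if the flood contains a strictly higher
    pixel or covers its entire mask component.  Equal-valued accepted
    plateaus sharing a flood merge into one report (smallest-first-pixel
    plateau); the reported position is the plateau pixel nearest the
    plateau centroid.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    mask = np.ones((H, W), bool) if mask is None else np.asarray(mask, bool)
    coords = [(r, c) for r in range(H) for c in range(W) if mask[r, c]]
    if not coords:
        return []

    def neighbors(r, c):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and mask[rr, cc]:
                    yield rr, cc

    comp_id: dict[tuple[int, int], int] = {}
    for start in coords:
        if start in comp_id:
            continue
        cid = len(set(comp_id.values()))
        dq = deque([start])
        comp_id[start] = cid
        while dq:
            r, c = dq.popleft()
            for nb in neighbors(r, c):
                if nb not in comp_id:
                    comp_id[nb] = cid
                    dq.append(nb)
    comp_sizes: dict[int, int] = {}
    for cid in comp_id.values():
        comp_sizes[cid] = comp_sizes.get(cid, 0) + 1

    seen: set[tuple[int, int]] = set()
    plateaus = []
    for start in coords:
        if start in seen:
            continue
        v = image[start]
        plat = {start}
        dq = deque([start])
        is_max = True
        while dq:
            r, c = dq.popleft()
            for nb in neighbors(r, c):
                if image[nb] == v:
                    if nb not in plat:
                        plat.add(nb)
                        dq.append(nb)
                elif image[nb] > v:
                    is_max = False
        seen |= plat
        if is_max:
            plateaus.append((v, sorted(plat)))

    accepted = []
    for v, plat in plateaus:
        thr = v - tol
        start = plat[0]
        flood: set[tuple[int, int]] = set()
        if image[start] > thr:
            dq = deque([start])
            flood.add(start)
            while dq:
                r, c = dq.popleft()
                for nb in neighbors(r, c):
                    if nb not in flood and image[nb] > thr:
                        flood.add(nb)
                        dq.append(nb)
        higher = any(image[p] > v for p in flood)
        whole = len(flood) == comp_sizes[comp_id[start]]
        if not higher and not whole:
            accepted.append((v, plat, flood))

    out = []
    used: set[int] = set()
    for i, (v, plat, flood) in enumerate(accepted):
        if i in used:
            continue
        group = [i]
        for j in range(i + 1, len(accepted)):
            vj, platj, _fj = accepted[j]
            if vj == v and flood and platj[0] in flood:
                group.append(j)
        used |= set(group)
        best = min(group, key=lambda g: accepted[g][1][0])
        px = np.array(accepted[best][1], dtype=float)
        cen = px.mean(axis=0)
        d2 = ((px - cen) ** 2).sum(axis=1)
        order = np.lexsort((px[:, 1], px[:, 0], d2))
        out.append(tuple(int(x) for x in px[order[0]]))
    return sorted(out)


def oracle_otsu(hist):
    """Exhaustive Otsu over an 8-bit histogram: loop over all 256 levels."""
    hist = np.asarray(hist, dtype=float)
    n = hist.sum()
    levels = np.arange(hist.size)
    best_t, best_var = None, -1.0
    for t in range(hist.size - 1):
        w0 = hist[: t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def two_peak_toy_image():
    """Peaks of 100 and 80 joined by a ridge of 70 on a 6x9 grid.

    The lower peak's prominence is 10: one maximum at tolerance 35, two at
    tolerance 5.
    """
    img = np.zeros((6, 9))
    img[2, 2] = 100.0
    img[2, 6] = 80.0
    img[2, 3:6] = 70.0
    return img


@pytest.fixture(scope="session")
def small_widefield_field():
    """A modest noisy wide-field field with known ground truth."""
    from halofoci import render_zstack, sample_cell_field, widefield_config

    config = widefield_config(image_shape_px=(768, 768), seed=11)
    cells, truth = sample_cell_field(config, 30, 2.5, seed=11)
    stack, _ = render_zstack(cells, config, rng=np.random.default_rng(12))
    return config, cells, truth, stack
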