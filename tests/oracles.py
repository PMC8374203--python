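"""Independent brute-force oracles used only by the test suite.

These deliberately take slow, elementary routes (level-set flooding,
union-find persistence, explicit morphology) so they cannot share a defect
with the library implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

S8 = np.ones((3, 3), dtype=int)


def count_prominent_maxima(img: np.ndarray, t: int, prominence: float) -> int:
    """Count maxima with prominence >= the given value by persistence.

    Processes integer levels from high to low with union-find; a component
    is born at its peak level and dies when it merges into a component with
    a higher (or equal, tie-broken) peak — its prominence is birth minus
    the merge level. Components that never merge have prominence equal to
    their peak height above the masked floor (0). Matches the library's
    documented conventions while sharing no code with it.
    """
    f = np.where(np.asarray(img) >= t, np.asarray(img, dtype=int), 0)
    if f.max() == f.min():
        return 0  # a single all-image plateau rises above nothing
    h, w = f.shape
    parent = {}
    birth = {}
    alive_prom = []

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    order = np.argsort(f.ravel(), kind="stable")[::-1]
    added = np.zeros(h * w, dtype=bool)
    for flat in order:
        v = f.ravel()[flat]
        if v <= 0:
            break
        y, x = divmod(int(flat), w)
        parent[flat] = flat
        birth[flat] = v
        added[flat] = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w):
                    continue
                nflat = ny * w + nx
                if not added[nflat]:
                    continue
                ra, rb = find(flat), find(nflat)
                if ra == rb:
                    continue
                # the component with the lower peak dies at this level
                if birth[ra] > birth[rb] or (
                    birth[ra] == birth[rb] and ra < rb
                ):
                    ra, rb = rb, ra
                alive_prom.append(birth[ra] - v)
                parent[ra] = rb
    # survivors: prominence = peak height over the floor
    roots = {find(a) for a in parent}
    for r in roots:
        alive_prom.append(birth[r])
    return sum(1 for p in alive_prom if p >= prominence)


def per_cell_means(img: np.ndarray, origin, cell_px, n_rows, n_cols) -> np.ndarray:
    """Per-grid-cell mean by explicit pixel loops."""
    out = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            acc = 0.0
            cnt = 0
            for i in range(origin[0] + r * cell_px, origin[0] + (r + 1) * cell_px):
                for j in range(origin[1] + c * cell_px, origin[1] + (c + 1) * cell_px):
                    acc += float(img[i, j])
                    cnt += 1
            out[r, c] = acc / cnt
    return out


def ols_three_point(points):
    """Closed-form OLS for small point sets (hand algebra, no scipy)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - slope * x - intercept
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1 - ss_res / ss_tot
    return slope, intercept, r2


def ball_opening_background(img: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background by explicit min/max loops with a ball surface.

    Erosion then dilation with b(y) = sqrt(r² − |y|²), edge pixels clamped
    (nearest). Quadratic-time reference for small images.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    r = int(np.ceil(radius))
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy * dy + dx * dx <= radius * radius:
                offsets.append((dy, dx, np.sqrt(radius**2 - dy * dy - dx * dx)))

    def clamp(i, n):
        return min(max(i, 0), n - 1)

    eroded = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(
                img[clamp(y + dy, h), clamp(x + dx, w)] - b for dy, dx, b in offsets
            )
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            out[y, x] = max(
                eroded[clamp(y + dy, h), clamp(x + dx, w)] + b for dy, dx, b in offsets
            )
    return out
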