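"""Independent brute-force reference implementations used only by tests.

Deliberately written with plain per-pair loops and, for the isotropic
correction, a different geometric algorithm (arc-interval measurement of
the circle inside the window) than the package's closed-form
inclusion–exclusion, so agreement is evidence rather than tautology.
"""

import math

import numpy as np


def circle_inside_fraction(cx, cy, d, win):
    """Fraction of the circle of radius d centred at (cx, cy) inside the
    rectangle, measured by splitting [0, 2pi) at every circle/edge
    crossing angle and testing each arc's midpoint."""
    cuts = [0.0]
    lo_c = (win.x_min - cx) / d
    hi_c = (win.x_max - cx) / d
    lo_s = (win.y_min - cy) / d
    hi_s = (win.y_max - cy) / d
    for c in (lo_c, hi_c):
        if -1.0 <= c <= 1.0:
            a = math.acos(c)
            cuts.extend([a % (2 * math.pi), (-a) % (2 * math.pi)])
    for s in (lo_s, hi_s):
        if -1.0 <= s <= 1.0:
            a = math.asin(s)
            cuts.extend([a % (2 * math.pi), (math.pi - a) % (2 * math.pi)])
    cuts = sorted(set(cuts)) + [2 * math.pi]
    inside = 0.0
    eps = 1e-12
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        px = cx + d * math.cos(mid)
        py = cy + d * math.sin(mid)
        if (win.x_min - eps <= px <= win.x_max + eps
                and win.y_min - eps <= py <= win.y_max + eps):
            inside += b - a
    return inside / (2 * math.pi)


def naive_kcross(img, type_i, type_j, radii, correction):
    """O(n^2) double-loop cross K-function over all ordered pairs."""
    pts_i = img.coords_of(type_i)
    pts_j = img.coords_of(type_j)
    n_i, n_j = len(pts_i), len(pts_j)
    same = type_i == type_j
    win = img.window
    area = win.area
    lx = win.x_max - win.x_min
    ly = win.y_max - win.y_min
    if n_i == 0 or n_j == 0 or (same and n_i < 2):
        return np.full(len(radii), np.nan)
    norm = n_i * (n_i - 1) if same else n_i * n_j
    out = []
    for r in radii:
        total = 0.0
        for a in range(n_i):
            for b in range(n_j):
                if same and a == b:
                    continue
                dx = pts_i[a, 0] - pts_j[b, 0]
                dy = pts_i[a, 1] - pts_j[b, 1]
                d = math.hypot(dx, dy)
                if d > r:
                    continue
                if correction == "none":
                    w = 1.0
                elif correction == "translation":
                    w = area / ((lx - abs(dx)) * (ly - abs(dy)))
                elif correction == "isotropic":
                    if d == 0.0:
                        w = 1.0
                    else:
                        w = 1.0 / circle_inside_fraction(
                            pts_i[a, 0], pts_i[a, 1], d, win
                        )
                else:
                    raise ValueError(correction)
                total += w
        out.append(area / norm * total)
    return np.asarray(out)


def naive_auc(null_p, diff_p):
    """Exhaustive pairwise Mann-Whitney AUC (difference = positive,
    ranked by ascending p)."""
    wins = 0.0
    for pd_ in diff_p:
        for pn in null_p:
            if pd_ < pn:
                wins += 1.0
            elif pd_ == pn:
                wins += 0.5
    return wins / (len(diff_p) * len(null_p))
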