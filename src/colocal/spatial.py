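"""Cross-type K and L functions and the co-localization score u.

For an image with ``n_i`` cells of type i and ``n_j`` of type j in a
window of area ``A``, the empirical cross K-function is

    K_ij(r) = A / (n_i n_j) * sum over ordered (i-cell, j-cell) pairs of
              1[d <= r] * e(d)

where ``e`` is an edge-correction weight compensating for neighbours
lost outside the window.  ``K_ij(r)`` is the (scaled) average number of
type-j cells within distance r of a typical type-i cell; under
independence of the two types it equals pi r^2.  The variance-stabilised
L-function L(r) = sqrt(K(r)/pi) equals r under that reference, and the
co-localization score

    u = sum over grid radii r' of [ L(r') - r' ]

is positive for attraction and negative for avoidance relative to
complete spatial randomness.

For the same-type case (i == j) the self-pair (a cell with itself at
distance zero) is excluded and the normaliser is ``n (n - 1)``, the
standard univariate convention.

Edge corrections implemented for rectangular windows:

``none``
    e = 1; biased near the boundary but exactly the raw pair count.
``translation`` (default)
    e = A / ((Lx - |dx|) (Ly - |dy|)): the reciprocal fraction of
    translations of the window that retain both endpoints.
``isotropic``
    e = 1 / (fraction of the circle of radius d centred on the i-cell
    that lies inside the window), via the exact inclusion–exclusion
    formula over the four edges and corners of the rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import CellImage, ImageSet, Window

__all__ = [
    "CORRECTIONS",
    "DEFAULT_RADII",
    "RadiusGrid",
    "CurveEstimate",
    "kcross",
    "lcross",
    "colocalization_score",
    "score_all",
    "write_scores",
]

CORRECTIONS = ("none", "translation", "isotropic")

#: Default radius grid: 10, 20, ..., 100 coordinate units.
DEFAULT_RADII = tuple(float(r) for r in range(10, 101, 10))


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing positive radii; a single radius is legal."""

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float] = DEFAULT_RADII):
        vals = tuple(float(v) for v in values)
        if len(vals) == 0:
            raise ValueError("radius grid is empty")
        arr = np.asarray(vals)
        if not (arr > 0).all():
            raise ValueError("radii must be positive")
        if len(vals) > 1 and not (np.diff(arr) > 0).all():
            raise ValueError("radii must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class CurveEstimate:
    """A K- or L-curve for one ordered type pair in one image.

    ``values`` are NaN throughout when either type count is zero: the
    statistic is undefined, not zero, and the missingness survives to the
    inference stage.
    """

    radii: RadiusGrid
    values: np.ndarray
    statistic: str  # "K" or "L"
    type_i: str
    type_j: str
    correction: str
    n_i: int = 0
    n_j: int = 0

    @property
    def defined(self) -> bool:
        return not np.isnan(self.values).all()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.radii.as_array(),
                self.statistic: self.values,
                "type_i": self.type_i,
                "type_j": self.type_j,
                "correction": self.correction,
            }
        )


def _isotropic_inside_fraction(
    px: np.ndarray, py: np.ndarray, d: np.ndarray, win: Window
) -> np.ndarray:
    """Fraction of the circle of radius d around (px, py) inside ``win``.

    Exact for any radius, by inclusion–exclusion on the four half-plane
    exterior arcs: each edge at distance ``a`` removes an arc of width
    2*arccos(a/d); two adjacent edges whose corner lies inside the circle
    double-count a quadrant arc of width arccos(a/d)+arccos(b/d)-pi/2.
    Opposite edges' arcs (each of half-width < pi/2, centred pi apart)
    never overlap, so the four-edge/four-corner expansion is complete.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.stack(
            [px - win.x_min, win.x_max - px, py - win.y_min, win.y_max - py]
        )
        ratio = np.clip(dist / d, -1.0, 1.0)
        half = np.arccos(ratio)  # half-width of exterior arc per edge
        half[dist >= d] = 0.0
        exterior = 2.0 * half.sum(axis=0)
        # corners: (left,bottom) (left,top) (right,bottom) (right,top)
        for ix, iy in ((0, 2), (0, 3), (1, 2), (1, 3)):
            overlap = half[ix] + half[iy] - np.pi / 2.0
            both = (half[ix] > 0) & (half[iy] > 0)
            exterior -= np.where(both, np.maximum(overlap, 0.0), 0.0)
    return 1.0 - exterior / (2.0 * np.pi)


def _pair_weights(
    pi_xy: np.ndarray,
    pj_xy: np.ndarray,
    d: np.ndarray,
    win: Window,
    correction: str,
) -> np.ndarray:
    """Edge-correction weight for every ordered (i-cell, j-cell) pair.

    ``d`` is the (n_i, n_j) distance matrix; the isotropic circle is
    centred on the i-cell of each pair.
    """
    if correction == "none":
        return np.ones_like(d)
    if correction == "translation":
        dx = np.abs(pi_xy[:, 0][:, None] - pj_xy[None, :, 0])
        dy = np.abs(pi_xy[:, 1][:, None] - pj_xy[None, :, 1])
        denom = (win.width - dx) * (win.height - dy)
        with np.errstate(divide="ignore"):
            w = win.area / denom
        w[denom <= 0] = np.nan  # pair separation exceeds the window: impossible
        return w
    if correction == "isotropic":
        px = np.broadcast_to(pi_xy[:, 0][:, None], d.shape)
        py = np.broadcast_to(pi_xy[:, 1][:, None], d.shape)
        frac = _isotropic_inside_fraction(px, py, d, win)
        w = np.ones_like(d)
        pos = d > 0
        w[pos] = 1.0 / frac[pos]
        return w
    raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")


def _k_values(
    d: np.ndarray, w: np.ndarray, r: np.ndarray, area: float, norm: int
) -> np.ndarray:
    """K(r) = area/norm * cumulative edge-corrected pair count within r.

    Evaluated for all radii at once by sorting the pair distances and
    taking a running sum of the weights.
    """
    dflat = d.ravel()
    # a translation weight is infinite only for pairs separated by the full
    # window extent; such pairs sit beyond any sensible radius — drop them
    wflat = np.nan_to_num(w.ravel(), nan=0.0, posinf=0.0)
    order = np.argsort(dflat, kind="stable")
    csum = np.concatenate([[0.0], np.cumsum(wflat[order])])
    idx = np.searchsorted(dflat[order], r, side="right")
    return area / norm * csum[idx]


def kcross(
    img: CellImage,
    type_i: str,
    type_j: str,
    grid: RadiusGrid | Sequence[float] = DEFAULT_RADII,
    correction: str = "translation",
) -> CurveEstimate:
    """Empirical cross (or same-type) K-function for one image.

    Returns an all-NaN curve, not an exception, when either type has zero
    cells in the image.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    if not isinstance(grid, RadiusGrid):
        grid = RadiusGrid(grid)
    pi_xy = img.coords_of(type_i)
    pj_xy = img.coords_of(type_j)
    n_i, n_j = len(pi_xy), len(pj_xy)
    same = type_i == type_j

    r = grid.as_array()
    undefined = n_i == 0 or n_j == 0 or (same and n_i < 2)
    if undefined:
        return CurveEstimate(grid, np.full(len(r), np.nan), "K", type_i, type_j,
                             correction, n_i, n_j)

    diff = pi_xy[:, None, :] - pj_xy[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    w = _pair_weights(pi_xy, pj_xy, d, img.window, correction)
    if same:
        np.fill_diagonal(w, 0.0)  # exclude self-pairs
        norm = n_i * (n_i - 1)
    else:
        norm = n_i * n_j
    k = _k_values(d, w, r, img.window.area, norm)
    return CurveEstimate(grid, k, "K", type_i, type_j, correction, n_i, n_j)


def lcross(k: CurveEstimate) -> CurveEstimate:
    """Variance-stabilised L-curve, L(r) = sqrt(K(r)/pi).

    NaN (undefined) K values propagate. Under complete spatial randomness
    the reference is L(r) = r.
    """
    if k.statistic != "K":
        raise ValueError("lcross expects a K curve")
    vals = np.asarray(k.values, dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise AssertionError("negative K value: internal invariant violated")
    return CurveEstimate(
        k.radii, np.sqrt(vals / np.pi), "L", k.type_i, k.type_j, k.correction,
        k.n_i, k.n_j,
    )


def colocalization_score(
    img: CellImage,
    type_i: str,
    type_j: str,
    grid: RadiusGrid | Sequence[float] = DEFAULT_RADII,
    correction: str = "translation",
) -> tuple[float, int, int]:
    """Score u = sum over grid radii of [L(r') - r'], with the pair counts.

    u > 0 means attraction of type j around type i relative to a random
    arrangement; u < 0 means avoidance. NaN when either count is zero.
    """
    k = kcross(img, type_i, type_j, grid, correction)
    l_curve = lcross(k)
    r = l_curve.radii.as_array()
    u = float(np.sum(l_curve.values - r)) if l_curve.defined else float("nan")
    return u, k.n_i, k.n_j


def _sparse_pair_weights(
    pi_xy: np.ndarray, pj_xy: np.ndarray, d: np.ndarray, win: Window, correction: str
) -> np.ndarray:
    """Edge weights for an explicit list of pairs (rows of pi_xy / pj_xy
    aligned with d); isotropic circles centre on the i-cell."""
    if correction == "none":
        return np.ones_like(d)
    if correction == "translation":
        dx = np.abs(pi_xy[:, 0] - pj_xy[:, 0])
        dy = np.abs(pi_xy[:, 1] - pj_xy[:, 1])
        denom = (win.width - dx) * (win.height - dy)
        with np.errstate(divide="ignore"):
            w = np.where(denom > 0, win.area / denom, 0.0)
        return w
    if correction == "isotropic":
        frac = _isotropic_inside_fraction(pi_xy[:, 0], pi_xy[:, 1], d, win)
        w = np.ones_like(d)
        pos = d > 0
        w[pos] = 1.0 / frac[pos]
        return w
    raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")


def _score_rows_for_image(
    img: CellImage,
    types: Sequence[str],
    grid: RadiusGrid,
    correction: str,
) -> list[dict]:
    """All ordered-pair scores for one image.

    Only pairs within the largest grid radius contribute to any K value,
    so distances are collected sparsely with a KD-tree; for the ``none``
    and ``translation`` corrections the (i,j) and (j,i) scores coincide
    (same pairs, same weights, same normaliser) and are computed once.
    """
    from scipy.spatial import cKDTree

    coords = {t: img.coords_of(t) for t in types}
    trees = {t: cKDTree(coords[t]) if len(coords[t]) else None for t in types}
    counts = {t: len(coords[t]) for t in types}
    r = grid.as_array()
    r_max = float(r[-1]) * (1 + 1e-12)
    area = img.window.area
    rows = []

    def score_from(d: np.ndarray, w: np.ndarray, norm: int) -> float:
        order = np.argsort(d, kind="stable")
        csum = np.concatenate([[0.0], np.cumsum(w[order])])
        idx = np.searchsorted(d[order], r, side="right")
        k = area / norm * csum[idx]
        return float(np.sum(np.sqrt(k / np.pi) - r))

    for a_idx, ti in enumerate(types):
        for tj in types[a_idx:]:
            ni, nj = counts[ti], counts[tj]
            same = ti == tj
            u_ij = u_ji = float("nan")
            if ni > 0 and nj > 0 and not (same and ni < 2):
                if same:
                    pairs = trees[ti].query_pairs(r_max, output_type="ndarray")
                    pi = coords[ti][pairs[:, 0]]
                    pj = coords[ti][pairs[:, 1]]
                    d = np.sqrt(((pi - pj) ** 2).sum(axis=1))
                    w_f = _sparse_pair_weights(pi, pj, d, img.window, correction)
                    if correction == "isotropic":
                        w_b = _sparse_pair_weights(pj, pi, d, img.window, correction)
                    else:
                        w_b = w_f
                    u_ij = score_from(
                        np.concatenate([d, d]), np.concatenate([w_f, w_b]),
                        ni * (ni - 1),
                    )
                else:
                    hits = trees[ti].sparse_distance_matrix(
                        trees[tj], r_max, output_type="ndarray"
                    )
                    pi = coords[ti][hits["i"]]
                    pj = coords[tj][hits["j"]]
                    d = hits["v"]
                    w = _sparse_pair_weights(pi, pj, d, img.window, correction)
                    u_ij = score_from(d, w, ni * nj)
                    if correction == "isotropic":
                        w_t = _sparse_pair_weights(pj, pi, d, img.window, correction)
                        u_ji = score_from(d, w_t, ni * nj)
                    else:
                        u_ji = u_ij
            rows.append({"image_id": img.image_id, "type_i": ti, "type_j": tj,
                         "u": u_ij, "n_i": ni, "n_j": nj})
            if not same:
                rows.append({"image_id": img.image_id, "type_i": tj, "type_j": ti,
                             "u": u_ji, "n_i": nj, "n_j": ni})
    return rows


def score_all(
    s: ImageSet,
    types: Sequence[str] | None = None,
    grid: RadiusGrid | Sequence[float] = DEFAULT_RADII,
    correction: str = "translation",
) -> pd.DataFrame:
    """Score table: one row per (image, ordered type pair), self-pairs included.

    Columns: ``image_id, type_i, type_j, u, n_i, n_j``. Rows where either
    count is zero carry ``u = NaN``.
    """
    if types is None:
        types = s.types()
    types = [str(t) for t in types]
    if not types:
        raise ValueError("no cell types to score")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    if not isinstance(grid, RadiusGrid):
        grid = RadiusGrid(grid)

    present: set[str] = set()
    for img in s.images.values():
        present.update(map(str, img.marks))
    missing = [t for t in types if t not in present]
    if missing:
        raise ValueError(f"cell type(s) absent from every image: {missing}")

    rows: list[dict] = []
    for iid in s.images:
        rows.extend(_score_rows_for_image(s.images[iid], types, grid, correction))
    df = pd.DataFrame(rows)
    # stable ordering: image, then pair
    order = {t: k for k, t in enumerate(types)}
    df = df.sort_values(
        ["image_id", "type_i", "type_j"],
        key=lambda c: c.map(order) if c.name in ("type_i", "type_j") else c,
        kind="stable",
    ).reset_index(drop=True)
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table as delimited text."""
    scores.to_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", index=False)
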