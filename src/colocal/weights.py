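"""Count-dependent variance modelling and inverse-variance weights.

The spread of the co-localization score u shrinks as the number of cells
of the pair grows, so score rows are not equally informative.  We model
this by regressing u^2 (a variance proxy) on the two pair counts under a
monotone non-increasing constraint, and weight each row by the inverse of
the fitted value: images with fewer cells of the pair get lower weight.

The monotone surface is an additive model on log counts,

    fitted_u2(n_i, n_j) = c + g_1(log n_i) + g_2(log n_j),

with each g_k a non-increasing piecewise-linear function, fitted by
constrained least squares (each g_k is a non-negative combination of
decreasing ramp bases, so monotonicity holds by construction and is also
probe-tested after every fit).  Predictions are clamped below by a
positive floor so weights stay finite, and extrapolation beyond the
fitted count range is flat (the monotone surface is extended by its edge
value).

Weights may be fitted from all type pairs pooled (the default, and the
better-conditioned choice for small studies) or per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

__all__ = ["VarianceModel", "fit_variance_surface", "compute_weights"]


def _ramp_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Non-decreasing ramp functions between consecutive knots.

    Column m rises linearly from 0 to 1 over [knots[m], knots[m+1]] and is
    flat outside; any non-negative combination is non-decreasing in t.
    """
    cols = []
    for a, b in zip(knots[:-1], knots[1:]):
        cols.append(np.clip((t - a) / (b - a), 0.0, 1.0))
    return np.column_stack(cols) if cols else np.zeros((len(t), 0))


def _knots(t: np.ndarray, max_knots: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, max_knots)
    k = np.unique(np.quantile(t, qs))
    return k


@dataclass
class VarianceModel:
    """Fitted monotone surface mapping pair counts to predicted u^2.

    ``predict`` is monotone non-increasing in each count argument and
    bounded below by ``floor`` (> 0), so the derived weights are finite.
    When ``pooling='per_pair'`` a separate surface is kept per ordered
    pair and ``predict`` requires the pair labels.
    """

    knots_i: np.ndarray
    knots_j: np.ndarray
    intercept: float
    coef_i: np.ndarray  # non-negative ramp coefficients (decrements)
    coef_j: np.ndarray
    floor: float
    pooling: str = "all_pairs"
    per_pair: dict | None = None
    fit_meta: dict = field(default_factory=dict)

    def _raw(self, n_i: np.ndarray, n_j: np.ndarray) -> np.ndarray:
        ti = np.log(np.maximum(np.asarray(n_i, float), 1.0))
        tj = np.log(np.maximum(np.asarray(n_j, float), 1.0))
        val = (
            self.intercept
            - _ramp_basis(np.atleast_1d(ti), self.knots_i) @ self.coef_i
            - _ramp_basis(np.atleast_1d(tj), self.knots_j) @ self.coef_j
        )
        return val

    def predict(self, n_i, n_j, type_i: str | None = None, type_j: str | None = None):
        """Fitted u^2 at the given pair counts (floored)."""
        if self.pooling == "per_pair":
            if type_i is None or type_j is None:
                raise ValueError("per-pair model requires the pair labels")
            sub = self.per_pair[(type_i, type_j)]
            return sub.predict(n_i, n_j)
        out = np.maximum(self._raw(n_i, n_j), self.floor)
        return out if np.ndim(n_i) else float(out[0])

    def as_grid(self, counts: np.ndarray | None = None) -> pd.DataFrame:
        """Fitted surface on a count grid, for plotting / export."""
        if counts is None:
            lo = float(np.exp(self.knots_i.min())) if len(self.knots_i) else 20.0
            hi = float(np.exp(self.knots_i.max())) if len(self.knots_i) else 400.0
            counts = np.unique(np.round(np.geomspace(max(lo, 1), max(hi, 2), 12)))
        rows = []
        for a in counts:
            for b in counts:
                rows.append({"n_i": a, "n_j": b, "fitted_u2": self.predict(a, b)})
        return pd.DataFrame(rows)


_MIN_SCORES = 20


def _fit_single(n_i: np.ndarray, n_j: np.ndarray, u2: np.ndarray,
                max_knots: int) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray, dict]:
    ti = np.log(np.maximum(n_i.astype(float), 1.0))
    tj = np.log(np.maximum(n_j.astype(float), 1.0))
    ki = _knots(ti, max_knots)
    kj = _knots(tj, max_knots)
    bi = _ramp_basis(ti, ki)
    bj = _ramp_basis(tj, kj)
    # columns: intercept (free), then negated ramps (coefficients >= 0)
    a = np.column_stack([np.ones(len(u2)), -bi, -bj])
    lb = np.concatenate([[-np.inf], np.zeros(bi.shape[1] + bj.shape[1])])
    ub = np.full(a.shape[1], np.inf)
    res = lsq_linear(a, u2, bounds=(lb, ub), tol=1e-12, lsmr_tol=1e-12)
    intercept = float(res.x[0])
    ci = res.x[1 : 1 + bi.shape[1]]
    cj = res.x[1 + bi.shape[1] :]
    meta = {"converged": bool(res.success), "cost": float(res.cost),
            "n_rows": int(len(u2)), "n_knots": (len(ki), len(kj))}
    return ki, kj, intercept, ci, cj, meta


def fit_variance_surface(
    scores: pd.DataFrame,
    pooling: str = "all_pairs",
    max_knots: int = 8,
    min_scores: int = _MIN_SCORES,
    floor_rel: float = 1e-3,
    floor_abs: float = 1e-12,
) -> VarianceModel:
    """Fit the monotone count-to-variance surface from a score table.

    Parameters
    ----------
    scores : DataFrame
        Output of :func:`colocal.spatial.score_all` (columns
        ``u, n_i, n_j, type_i, type_j``). Undefined rows (NaN u) are
        ignored.
    pooling : "all_pairs" or "per_pair"
        Pool scores from every ordered pair into one surface (default;
        used for all headline analyses) or fit one surface per pair.
    """
    if pooling not in ("all_pairs", "per_pair"):
        raise ValueError(f"unknown pooling {pooling!r}")
    ok = scores.dropna(subset=["u"])
    ok = ok[(ok["n_i"] >= 1) & (ok["n_j"] >= 1)]
    if len(ok) < min_scores:
        raise ValueError(
            f"only {len(ok)} defined scores (< {min_scores}); pool across pairs "
            "(pooling='all_pairs') or run an unweighted analysis"
        )

    if pooling == "per_pair":
        per = {}
        for (ti_lab, tj_lab), grp in ok.groupby(["type_i", "type_j"]):
            if len(grp) < min_scores:
                raise ValueError(
                    f"pair ({ti_lab}, {tj_lab}) has only {len(grp)} defined scores "
                    f"(< {min_scores}); use pooling='all_pairs'"
                )
            per[(ti_lab, tj_lab)] = fit_variance_surface(
                grp, "all_pairs", max_knots, min_scores, floor_rel, floor_abs
            )
        any_model = next(iter(per.values()))
        return VarianceModel(
            any_model.knots_i, any_model.knots_j, any_model.intercept,
            any_model.coef_i, any_model.coef_j, any_model.floor,
            pooling="per_pair", per_pair=per,
            fit_meta={"pairs": len(per)},
        )

    u2 = (ok["u"].to_numpy(float)) ** 2
    ki, kj, intercept, ci, cj, meta = _fit_single(
        ok["n_i"].to_numpy(float), ok["n_j"].to_numpy(float), u2, max_knots
    )
    if np.allclose(u2, u2[0]):
        meta["constant_input"] = True
    model = VarianceModel(ki, kj, intercept, ci, cj, floor=1.0,
                          pooling="all_pairs", fit_meta=meta)
    fitted = model._raw(ok["n_i"].to_numpy(float), ok["n_j"].to_numpy(float))
    med = float(np.median(np.maximum(fitted, 0.0)))
    model.floor = max(floor_rel * med, floor_abs)
    return model


def compute_weights(model: VarianceModel, scores: pd.DataFrame) -> pd.Series:
    """Inverse fitted-variance weights, normalised to mean 1 over defined rows.

    Rows with undefined u get weight 0 (they are dropped by the models
    downstream). The downstream linear and mixed models are invariant to
    a global weight rescale, so the mean-1 normalisation is cosmetic.
    """
    defined = scores["u"].notna().to_numpy()
    w = np.zeros(len(scores))
    if model.pooling == "per_pair":
        for (ti_lab, tj_lab), grp in scores.groupby(["type_i", "type_j"]):
            sel = grp.index[grp["u"].notna()]
            if len(sel):
                pred = model.predict(
                    scores.loc[sel, "n_i"].to_numpy(float),
                    scores.loc[sel, "n_j"].to_numpy(float),
                    ti_lab, tj_lab,
                )
                w[scores.index.get_indexer(sel)] = 1.0 / np.asarray(pred)
    else:
        pred = model.predict(
            scores.loc[defined, "n_i"].to_numpy(float),
            scores.loc[defined, "n_j"].to_numpy(float),
        )
        w[defined] = 1.0 / np.asarray(pred)
    if defined.any():
        w = w / w[defined].mean()
    return pd.Series(w, index=scores.index, name="weight")


def write_weights(scores: pd.DataFrame, weights: pd.Series, path: str | Path) -> None:
    out = scores[["image_id", "type_i", "type_j", "n_i", "n_j"]].copy()
    out["weight"] = weights
    out.to_csv(path, index=False)
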