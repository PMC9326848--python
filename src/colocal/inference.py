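"""Testing condition effects on co-localization scores.

For each ordered cell-type pair the score table contributes one value u
per image.  The condition effect is estimated with either

* a weighted linear model,   u_i  = a + b x_i + G W + e_i,  or
* a random-intercept model,  u_ij = a_i + b x_i + G W + e_ij,

where x is the condition (categorical with treatment contrasts against a
reference level, or continuous), W are optional covariates, and a_i is a
subject-level random intercept capturing correlation between images from
the same subject.  Per-row precision weights w enter as residual variance
sigma^2 / w.  The mixed model is fitted by REML, profiling a
one-dimensional criterion over the variance ratio tau^2/sigma^2 with a
deterministic bounded search; p-values for the fixed effect use
Satterthwaite's effective degrees of freedom,

    df = 2 Var(c'beta)^2 / (g' A g),

with g the gradient of the contrast variance in the variance components
(tau^2, sigma^2) and A their REML asymptotic covariance.

The user-facing entry point is :class:`CoLocModel`, a model object built
from an :class:`~colocal.data_model.ImageSet` whose :meth:`CoLocModel.fit`
returns a :class:`CoLocResults` carrying per-pair estimates, standard
errors, degrees of freedom, raw and adjusted p-values and a summary
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from . import __version__ as _pkg_version
from .data_model import ImageSet, validate_imageset
from .spatial import DEFAULT_RADII, RadiusGrid, score_all
from .weights import VarianceModel, compute_weights, fit_variance_surface

__all__ = [
    "DesignSpec",
    "PairResult",
    "CoLocModel",
    "CoLocResults",
    "fit_weighted_linear",
    "fit_weighted_mixed",
    "MixedFit",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class DesignSpec:
    """What is being tested and how.

    condition : name of the tested variable (categorical or continuous)
    covariates : extra fixed-effect columns
    subject : grouping column for random intercepts (None -> linear model)
    weights_mode : "fitted" (inverse fitted-variance weights) or "none"
    reference : reference level for a categorical condition (default: first
        sorted level)
    """

    condition: str = "condition"
    covariates: tuple[str, ...] = ()
    subject: str | None = "subject_id"
    weights_mode: str = "fitted"
    reference: object | None = None


# ---------------------------------------------------------------------------
# weighted linear model


@dataclass
class PairResult:
    """Condition-effect estimate for one ordered type pair (one contrast)."""

    type_i: str
    type_j: str
    contrast: str
    beta: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adjusted: float
    n_used: int
    n_dropped: int
    model: str  # "linear" or "mixed"
    random_intercept_var: float = np.nan
    residual_var: float = np.nan
    boundary: bool = False

    @property
    def direction(self) -> float:
        return float(np.sign(self.beta)) if np.isfinite(self.beta) else np.nan

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p_raw)


def _untestable(type_i, type_j, contrast, n_total, model) -> PairResult:
    nan = float("nan")
    return PairResult(type_i, type_j, contrast, nan, nan, nan, nan, nan, nan,
                      0, n_total, model)


def fit_weighted_linear(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, xnames: Sequence[str]
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """Weighted least squares with precision weights (invariant to a global
    rescale of ``w``)."""
    return sm.WLS(y, X, weights=w).fit()


# ---------------------------------------------------------------------------
# random-intercept REML


@dataclass
class MixedFit:
    """REML fit of a weighted random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray  # at the REML variance-component estimates
    sigma2: float
    tau2: float
    df: np.ndarray  # Satterthwaite, per coefficient
    n: int
    p: int
    n_groups: int
    boundary: bool
    converged: bool
    xnames: tuple[str, ...]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


class _RandomInterceptREML:
    """Profiled REML machinery for y = X b + Z a + e with per-row
    precision weights: Var(e_row) = sigma^2 / w_row, a ~ N(0, tau^2 I).

    With lam = tau^2/sigma^2 and H = W^{-1} + lam Z Z', all the profiled
    quantities reduce (via Woodbury, block-diagonal in subjects) to
    per-subject weighted sums, so one criterion evaluation is O(G p^2).
    """

    def __init__(self, y, X, groups, w):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.w = np.asarray(w, float)
        codes, uniq = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.n, self.p = self.X.shape
        self.n_groups = len(uniq)
        wx = self.X * self.w[:, None]
        self.XtWX = self.X.T @ wx
        self.XtWy = self.X.T @ (self.w * self.y)
        self.ytWy = float(self.y @ (self.w * self.y))
        self.sum_log_w = float(np.sum(np.log(self.w)))
        # per-group aggregates
        g = self.n_groups
        self.A = np.zeros((g, self.p))  # X_s' w_s
        np.add.at(self.A, codes, wx)
        self.b = np.bincount(codes, weights=self.w * self.y, minlength=g)
        self.s = np.bincount(codes, weights=self.w, minlength=g)

    def _pieces(self, lam: float):
        kappa = lam / (1.0 + lam * self.s)
        XtHX = self.XtWX - (self.A * kappa[:, None]).T @ self.A
        XtHy = self.XtWy - self.A.T @ (kappa * self.b)
        ytHy = self.ytWy - float(kappa @ self.b**2)
        logdet_h = float(np.sum(np.log1p(lam * self.s))) - self.sum_log_w
        return XtHX, XtHy, ytHy, logdet_h

    def profile(self, lam: float):
        XtHX, XtHy, ytHy, logdet_h = self._pieces(lam)
        beta = np.linalg.solve(XtHX, XtHy)
        rss = max(ytHy - float(beta @ XtHy), 1e-300)
        sigma2 = rss / (self.n - self.p)
        sign, logdet_xhx = np.linalg.slogdet(XtHX)
        crit = (self.n - self.p) * np.log(sigma2) + logdet_h + logdet_xhx
        return crit, beta, sigma2, XtHX

    def minus2_reml(self, tau2: float, sigma2: float) -> float:
        """-2 REML log-likelihood (up to a constant) at given components."""
        lam = tau2 / sigma2
        XtHX, XtHy, ytHy, logdet_h = self._pieces(lam)
        beta = np.linalg.solve(XtHX, XtHy)
        rss = max(ytHy - float(beta @ XtHy), 1e-300)
        sign, logdet_xhx = np.linalg.slogdet(XtHX)
        return (
            self.n * np.log(sigma2) + logdet_h
            + logdet_xhx - self.p * np.log(sigma2)
            + rss / sigma2
        )

    def contrast_var(self, c: np.ndarray, tau2: float, sigma2: float) -> float:
        lam = tau2 / sigma2
        XtHX, *_ = self._pieces(lam)
        return float(sigma2 * c @ np.linalg.solve(XtHX, c))


def _satterthwaite_df(
    reml: _RandomInterceptREML, c: np.ndarray, tau2: float, sigma2: float
) -> float:
    """df = 2 f^2 / (g' A g) with f the contrast variance, g its gradient
    in (tau^2, sigma^2) and A the REML covariance of the components.

    Derivatives are numerical (central where the component is interior,
    forward at the tau^2 = 0 boundary)."""
    theta = np.array([tau2, sigma2], float)
    steps = np.maximum(1e-4 * np.abs(theta), 1e-4 * sigma2)

    def grad(fun):
        g = np.zeros(2)
        for k in range(2):
            h = steps[k]
            if theta[k] - h > 0:
                g[k] = (fun(*_bump(theta, k, h)) - fun(*_bump(theta, k, -h))) / (2 * h)
            else:
                g[k] = (fun(*_bump(theta, k, h)) - fun(*theta)) / h
        return g

    def _bump(th, k, h):
        out = th.copy()
        out[k] += h
        return out

    f0 = reml.contrast_var(c, *theta)
    g = grad(lambda t2, s2: reml.contrast_var(c, t2, s2))

    # observed information of the REML criterion (Hessian of -log restricted
    # likelihood = 0.5 * Hessian of minus2_reml)
    def m2(t2, s2):
        return reml.minus2_reml(max(t2, 0.0), max(s2, 1e-300))

    hess = np.zeros((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ha, hb = steps[a], steps[b]
            if a == b:
                lo = theta[a] - ha
                if lo > 0:
                    hess[a, a] = (
                        m2(*_bump(theta, a, ha)) - 2 * m2(*theta) + m2(*_bump(theta, a, -ha))
                    ) / ha**2
                else:
                    hess[a, a] = (
                        m2(*_bump(theta, a, 2 * ha)) - 2 * m2(*_bump(theta, a, ha)) + m2(*theta)
                    ) / ha**2
            else:
                tpp = _bump(_bump(theta, a, ha), b, hb)
                tpm = _bump(_bump(theta, a, ha), b, -hb)
                tmp = _bump(_bump(theta, a, -ha), b, hb)
                tmm = _bump(_bump(theta, a, -ha), b, -hb)
                if theta[a] - ha <= 0 or theta[b] - hb <= 0:
                    # one-sided in the boundary direction
                    t00 = theta
                    t10 = _bump(theta, a, ha)
                    t01 = _bump(theta, b, hb)
                    hess[a, b] = hess[b, a] = (
                        m2(*tpp) - m2(*t10) - m2(*t01) + m2(*t00)
                    ) / (ha * hb)
                else:
                    hess[a, b] = hess[b, a] = (
                        m2(*tpp) - m2(*tpm) - m2(*tmp) + m2(*tmm)
                    ) / (4 * ha * hb)
    info = 0.5 * hess
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        return float(reml.n - reml.p)
    denom = float(g @ cov @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(reml.n - reml.p)
    df = 2.0 * f0**2 / denom
    return float(np.clip(df, 1e-6, reml.n - reml.p))


def fit_weighted_mixed(
    y: np.ndarray,
    X: np.ndarray,
    groups: Sequence,
    w: np.ndarray,
    xnames: Sequence[str] | None = None,
) -> MixedFit:
    """REML fit of the weighted random-intercept model.

    The variance ratio lam = tau^2/sigma^2 is profiled: a deterministic
    coarse log-grid scan brackets the optimum, then a bounded scalar
    minimisation refines it to tolerance 1e-10. lam = 0 (no subject
    variance) is a valid boundary solution and is flagged.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    w = np.asarray(w, float)
    if xnames is None:
        xnames = [f"x{k}" for k in range(X.shape[1])]
    reml = _RandomInterceptREML(y, X, groups, w)

    grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e8, 49)])
    crits = np.array([reml.profile(l)[0] for l in grid])
    best = int(np.argmin(crits))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    converged = True
    if hi > lo:
        res = minimize_scalar(
            lambda l: reml.profile(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat = float(res.x)
        if reml.profile(lam_hat)[0] > crits[best]:
            lam_hat = float(grid[best])
        converged = bool(getattr(res, "success", True))
    else:  # pragma: no cover - degenerate bracket
        lam_hat = float(grid[best])
    # snap to the boundary when the refined optimum is statistically
    # indistinguishable from 0 (flat profiles drift by float cancellation)
    crit_hat = reml.profile(lam_hat)[0]
    if reml.profile(0.0)[0] <= crit_hat + 1e-6 * (1.0 + abs(crit_hat)):
        lam_hat = 0.0

    crit, beta, sigma2, XtHX = reml.profile(lam_hat)
    tau2 = lam_hat * sigma2
    cov_beta = sigma2 * np.linalg.inv(XtHX)
    p = X.shape[1]
    df = np.empty(p)
    if lam_hat == 0.0:
        # boundary fit: the model collapses to weighted least squares and
        # the exact residual df applies (matches lmerTest's behaviour)
        df[:] = reml.n - p
    else:
        for k in range(p):
            c = np.zeros(p)
            c[k] = 1.0
            df[k] = _satterthwaite_df(reml, c, tau2, sigma2)
    return MixedFit(
        beta=beta, cov_beta=cov_beta, sigma2=float(sigma2), tau2=float(tau2),
        df=df, n=reml.n, p=p, n_groups=reml.n_groups,
        boundary=(lam_hat == 0.0), converged=converged, xnames=tuple(xnames),
    )


# ---------------------------------------------------------------------------
# design-matrix construction


def _build_design(
    meta: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Fixed-effect matrix from per-row metadata.

    Returns (X, column names, names of the condition-contrast columns).
    Categorical condition -> treatment coding against ``design.reference``.
    """
    cond = meta[design.condition]
    cols: list[pd.Series] = []
    names: list[str] = []
    contrast_names: list[str] = []
    if pd.api.types.is_numeric_dtype(cond) and cond.nunique() > 2:
        cols.append(cond.astype(float))
        names.append(design.condition)
        contrast_names.append(design.condition)
    else:
        levels = sorted(map(str, cond.astype(str).unique()))
        ref = str(design.reference) if design.reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} not among condition levels {levels}"
            )
        for lev in levels:
            if lev == ref:
                continue
            name = f"{design.condition}[{lev}-{ref}]"
            cols.append((cond.astype(str) == lev).astype(float))
            names.append(name)
            contrast_names.append(name)
    for cov in design.covariates:
        v = meta[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.astype(float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(v.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].astype(float))
                names.append(c)
    X = np.column_stack([np.ones(len(meta))] + [c.to_numpy() for c in cols])
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns: {names}); "
            "check for collinear covariates or single-level factors"
        )
    return X, names, contrast_names


# ---------------------------------------------------------------------------
# results container


@dataclass
class CoLocResults:
    """Results of a differential co-localization analysis.

    ``pair_results`` holds one :class:`PairResult` per ordered type pair
    and condition contrast; ``scores`` and ``weights`` are the stage-(i)
    and stage-(ii) intermediates; ``config`` echoes every analysis choice
    for provenance.
    """

    pair_results: list[PairResult]
    scores: pd.DataFrame
    weights: pd.Series | None
    variance_model: VarianceModel | None
    config: dict
    adjustment: str = "none"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.pair_results])
        df["direction"] = np.sign(df["beta"])
        return df

    @property
    def table(self) -> pd.DataFrame:
        return self.to_frame()

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Differential co-localization analysis",
            f"  model: {self.config.get('model')}   weights: {self.config.get('weights_mode')}",
            f"  radii: {self.config.get('radii')}   correction: {self.config.get('correction')}",
            f"  condition: {self.config.get('condition')}   adjustment: {self.adjustment}",
            "",
            df[["type_i", "type_j", "contrast", "beta", "se", "df", "t",
                "p_raw", "p_adjusted", "n_used"]].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def signed_logp_matrix(self, contrast: str | None = None) -> pd.DataFrame:
        """M[i, j] = sign(beta) * (-log10 p_raw); rows are the 'from' type i,
        columns the 'to' type j. Untestable pairs are NaN."""
        df = self.to_frame()
        if contrast is not None:
            df = df[df["contrast"] == contrast]
        elif df["contrast"].nunique() > 1:
            raise ValueError(
                f"multiple contrasts present ({sorted(df['contrast'].unique())}); "
                "pass contrast="
            )
        types_i = sorted(df["type_i"].unique())
        types_j = sorted(df["type_j"].unique())
        mat = pd.DataFrame(np.nan, index=types_i, columns=types_j)
        for row in df.itertuples():
            if np.isfinite(row.p_raw):
                val = np.sign(row.beta) * (-np.log10(max(row.p_raw, 1e-300)))
                mat.loc[row.type_i, row.type_j] = val
        mat.index.name = "from"
        mat.columns.name = "to"
        return mat

    def plot_heatmap(self, path: str | Path | None = None, contrast: str | None = None):
        """Signed -log10 p heatmap (positive = increased co-localization)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        mat = self.signed_logp_matrix(contrast)
        vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
        fig, ax = plt.subplots(figsize=(1.0 + 0.6 * mat.shape[1], 1.0 + 0.6 * mat.shape[0]))
        im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_xlabel("to (type j)")
        ax.set_ylabel("from (type i)")
        fig.colorbar(im, ax=ax, label="sign(beta) x -log10 p")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig

    def export(self, directory: str | Path, contrast: str | None = None) -> None:
        """Write the results table, the signed -log10 p matrix and the
        heatmap image into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "results.csv", index=False)
        if contrast is None and self.to_frame()["contrast"].nunique() == 1:
            contrast = self.to_frame()["contrast"].iloc[0]
        mats = (
            [contrast] if contrast is not None
            else sorted(self.to_frame()["contrast"].unique())
        )
        for c in mats:
            safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in c)
            self.signed_logp_matrix(c).to_csv(directory / f"signed_logp_{safe}.csv")
            self.plot_heatmap(directory / f"heatmap_{safe}.png", contrast=c)


def adjust_pvalues(results: CoLocResults, method: str = "BH") -> CoLocResults:
    """Adjust raw p-values across all tested pairs (Benjamini–Hochberg
    step-up, or copy raw when method='none')."""
    if method not in ("none", "BH"):
        raise ValueError(f"unknown adjustment {method!r}")
    ps = np.array([r.p_raw for r in results.pair_results])
    ok = np.isfinite(ps)
    adj = np.full(len(ps), np.nan)
    if method == "none":
        adj[ok] = ps[ok]
    elif ok.any():
        adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for r, a in zip(results.pair_results, adj):
        r.p_adjusted = float(a)
    results.adjustment = method
    return results


# ---------------------------------------------------------------------------
# the model object


class CoLocModel:
    """Differential cell-type co-localization model for an imaging study.

    Parameters
    ----------
    imageset : ImageSet
        The study: images, subjects, condition, covariates.
    condition : str
        Metadata column holding the tested variable.
    subject : str or None
        Metadata column holding the subject grouping. When given and any
        subject has more than one image, a random-intercept mixed model
        is used (overridable via ``fit(model=...)``).
    types : sequence of str, optional
        Cell types to analyse (default: all types present).
    radii : sequence of float
        Radius grid for the co-localization score (default 10..100
        step 10, coordinate units).
    correction : str
        Edge correction: "translation" (default), "isotropic" or "none".

    Examples
    --------
    >>> model = CoLocModel(study, condition="condition", subject="subject_id")
    >>> res = model.fit(weights="fitted")
    >>> print(res.summary())
    """

    def __init__(
        self,
        imageset: ImageSet,
        condition: str = "condition",
        subject: str | None = "subject_id",
        covariates: Sequence[str] = (),
        types: Sequence[str] | None = None,
        radii: Sequence[float] = DEFAULT_RADII,
        correction: str = "translation",
        reference: object | None = None,
    ):
        self.imageset = imageset
        self.design = DesignSpec(
            condition=condition, covariates=tuple(covariates), subject=subject,
            reference=reference,
        )
        self.types = list(types) if types is not None else imageset.types()
        self.grid = radii if isinstance(radii, RadiusGrid) else RadiusGrid(radii)
        self.correction = correction
        report = validate_imageset(imageset, self.types)
        if not report.ok:
            raise ValueError(
                "condition is not constant within subject(s): "
                f"{report.inconsistent_subjects}"
            )
        self._report = report

    @classmethod
    def from_dataframe(
        cls,
        cells: pd.DataFrame,
        column_map: Mapping[str, str] | None = None,
        window=None,
        **kwargs,
    ) -> "CoLocModel":
        """Build the model from a long cell table (one row per cell)."""
        import io
        from .data_model import load_cells

        buf = io.StringIO()
        cells.to_csv(buf, index=False)
        buf.seek(0)
        s = load_cells(buf, column_map=column_map,
                       window_policy=window if window is not None else "bounding_box")
        return cls(s, **kwargs)

    # -- pipeline stages -----------------------------------------------------

    def _scores(self, scores: pd.DataFrame | None = None) -> pd.DataFrame:
        if scores is None:
            scores = score_all(self.imageset, self.types, self.grid, self.correction)
        return scores

    def fit(
        self,
        weights: str = "fitted",
        model: str = "auto",
        adjustment: str = "none",
        pooling: str = "all_pairs",
        scores: pd.DataFrame | None = None,
    ) -> CoLocResults:
        """Run scoring, weighting and per-pair testing.

        Parameters
        ----------
        weights : "fitted" or "none"
        model : "auto", "linear" or "mixed"
            "auto" selects mixed iff a subject grouping exists and any
            subject has more than one image.
        adjustment : "none" (default; raw p-values are reported) or "BH"
        pooling : weight-fitting pooling, "all_pairs" (default) or "per_pair"
        scores : precomputed score table, to skip stage (i)
        """
        if weights not in ("fitted", "none"):
            raise ValueError(f"unknown weights mode {weights!r}")
        scores = self._scores(scores)
        meta = self.imageset.metadata_frame().set_index("image_id")

        vmodel = None
        if weights == "fitted":
            vmodel = fit_variance_surface(scores, pooling=pooling)
            w = compute_weights(vmodel, scores)
        else:
            w = pd.Series(
                np.where(scores["u"].notna(), 1.0, 0.0), index=scores.index,
                name="weight",
            )

        use_subject = self.design.subject is not None
        if model == "auto":
            if use_subject:
                n_per = meta["subject_id"].value_counts()
                model = "mixed" if (len(n_per) and (n_per > 1).any()) else "linear"
            else:
                model = "linear"
        if model == "mixed" and not use_subject:
            raise ValueError("mixed model requested but no subject grouping given")
        if model not in ("linear", "mixed"):
            raise ValueError(f"unknown model {model!r}")

        results: list[PairResult] = []
        for (ti, tj), grp in scores.groupby(["type_i", "type_j"], sort=False):
            rows = grp.join(meta, on="image_id")
            rows = rows.assign(weight=w.loc[grp.index])
            usable = rows["u"].notna() & (rows["weight"] > 0)
            usable &= rows[self.design.condition].notna()
            used = rows[usable]
            n_total = len(rows)
            if len(used) == 0 or used[self.design.condition].nunique() < 2:
                results.append(_untestable(ti, tj, self.design.condition,
                                           n_total, model))
                continue
            X, names, contrast_names = _build_design(used, self.design)
            if len(used) < X.shape[1] + 2:
                for cname in contrast_names or [self.design.condition]:
                    results.append(_untestable(ti, tj, cname, n_total, model))
                continue
            y = used["u"].to_numpy(float)
            wv = used["weight"].to_numpy(float)
            if model == "linear":
                fit = fit_weighted_linear(y, X, wv, names)
                for cname in contrast_names:
                    k = names.index(cname)
                    results.append(PairResult(
                        ti, tj, cname,
                        beta=float(fit.params[k]), se=float(fit.bse[k]),
                        df=float(fit.df_resid), t=float(fit.tvalues[k]),
                        p_raw=float(fit.pvalues[k]), p_adjusted=np.nan,
                        n_used=len(used), n_dropped=n_total - len(used),
                        model="linear",
                        residual_var=float(fit.scale),
                    ))
            else:
                groups = used["subject_id"].to_numpy()
                fit = fit_weighted_mixed(y, X, groups, wv, names)
                for cname in contrast_names:
                    k = names.index(cname)
                    se = float(fit.se[k])
                    tval = float(fit.beta[k] / se)
                    p = float(2 * stats.t.sf(abs(tval), fit.df[k]))
                    results.append(PairResult(
                        ti, tj, cname,
                        beta=float(fit.beta[k]), se=se, df=float(fit.df[k]),
                        t=tval, p_raw=p, p_adjusted=np.nan,
                        n_used=len(used), n_dropped=n_total - len(used),
                        model="mixed",
                        random_intercept_var=fit.tau2, residual_var=fit.sigma2,
                        boundary=fit.boundary,
                    ))

        config = {
            "condition": self.design.condition,
            "covariates": list(self.design.covariates),
            "subject": self.design.subject,
            "reference": self.design.reference,
            "types": self.types,
            "radii": list(self.grid.values),
            "correction": self.correction,
            "weights_mode": weights,
            "pooling": pooling if weights == "fitted" else None,
            "model": model,
            "adjustment": adjustment,
            "version": _pkg_version,
        }
        out = CoLocResults(results, scores, w if weights == "fitted" else None,
                           vmodel, config)
        return adjust_pvalues(out, adjustment)
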