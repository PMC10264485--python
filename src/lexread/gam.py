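"""Penalized regression with a tensor-product interaction surface.

The model for a log-transformed reading time y is

    y = b0 + b_len * length + b_freq * log_frequency + b_pos * position
        + f(osc, surprisal) + z_subject + z_word + eps

where ``f`` is either a tensor-product smooth (cubic B-spline marginal bases
with second-order difference penalties, one smoothing parameter per
direction, sum-to-zero constrained) or a parametric bilinear term
``[osc, surprisal, osc*surprisal]``, and ``z_subject``/``z_word`` are
ridge-penalized intercepts approximating spline random effects.

Smoothing parameters are chosen by generalized cross-validation,

    GCV = n * RSS / (n - edf)^2,

minimized by coordinate-wise golden-section search over log10(lambda).
Effective degrees of freedom of a term are the trace of its block of
(X'X + S)^{-1} X'X.  Standard errors come from the Bayesian posterior
covariance sigma^2 (X'X + S)^{-1}; p-values for smooth terms use an
approximate F reference on edf — the table structure of mixed GAM software,
not its exact machinery.

Also provided: linear-vs-tensor goodness-of-fit comparison, model criticism
(trim |standardized residual| > 2.5 SD and refit) and prediction of the
fitted interaction surface on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ModelSpec",
    "Design",
    "build_design",
    "PenalizedGAM",
    "FitResult",
    "fit_penalized",
    "ComparisonResult",
    "compare_forms",
    "model_criticism",
    "SurfaceGrid",
]

LOG10_LAMBDA_BOUNDS = (-4.0, 8.0)


# ---------------------------------------------------------------------------
# basis construction


def bspline_basis(
    x: np.ndarray, k: int, xmin: float, xmax: float, degree: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with ``k`` functions on [xmin, xmax].

    Eilers-Marx construction: one uniform knot sequence extended ``degree``
    intervals beyond each boundary, so that coefficient sequences that are
    polynomial in the knot index reproduce the same polynomial in x — the
    null space of an order-2 difference penalty is then exactly the linear
    functions.  Returns (n, k) design columns and the knot vector;
    evaluation outside the range extrapolates the polynomial pieces.
    """
    if k < degree + 1:
        raise ValueError(f"basis size {k} below minimum {degree + 1}")
    if not xmax > xmin:
        raise ValueError("degenerate covariate range: all values equal")
    h = (xmax - xmin) / (k - degree)
    knots = xmin + h * (np.arange(k + degree + 1) - degree)
    B = BSpline.design_matrix(
        np.asarray(x, dtype=float), knots, degree, extrapolate=True
    ).toarray()
    return B, knots


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """S = D'D for the ``order``-th difference matrix on k coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _row_kronecker(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (tensor) product of two bases."""
    n = A.shape[0]
    return (A[:, :, None] * B[:, None, :]).reshape(n, -1)


# ---------------------------------------------------------------------------
# model specification and design


@dataclass
class ModelSpec:
    """Configuration of the reading-time regression."""

    dv_name: str = "log_dv"
    linear_terms: tuple[str, ...] = ("length", "log_frequency", "position")
    interaction_form: str = "tensor"  # or "linear"
    k_osc: int = 5
    k_surprisal: int = 5
    penalty_order: int = 2
    random_effects: bool = True
    smoothing_selection: str = "gcv"
    max_iter: int = 20
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.interaction_form not in ("tensor", "linear"):
            raise ValueError(f"unknown interaction form {self.interaction_form!r}")
        if self.interaction_form == "tensor" and (
            self.k_osc < 4 or self.k_surprisal < 4
        ):
            raise ValueError("marginal basis sizes must be >= 4")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class Term:
    name: str
    start: int
    stop: int
    penalized: bool
    is_smooth: bool
    # block-local penalty matrices; each receives its own smoothing parameter
    penalties: list[np.ndarray] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass
class Design:
    """Assembled model matrix, term layout and embedded penalties."""

    X: np.ndarray
    terms: list[Term]
    column_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def penalty_count(self) -> int:
        return sum(len(t.penalties) for t in self.terms)

    def full_penalties(self) -> list[np.ndarray]:
        """Each penalty embedded in the full coefficient space."""
        p = self.X.shape[1]
        out = []
        for t in self.terms:
            for S in t.penalties:
                full = np.zeros((p, p))
                full[t.start : t.stop, t.start : t.stop] = S
                out.append(full)
        return out


def build_design(records: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build model and penalty matrices for one record table.

    Columns required: the linear covariates named in ``spec.linear_terms``,
    ``osc``, ``surprisal``, and (when random effects are on) ``subject_id``
    and ``word_type``.
    """
    n = len(records)
    if n == 0:
        raise ValueError("no records")
    blocks: list[np.ndarray] = []
    terms: list[Term] = []
    names: list[str] = []
    meta: dict = {}
    col = 0

    def covariate(name: str) -> np.ndarray:
        x = np.asarray(records[name], dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in covariate {name!r}")
        return x

    # parametric block: intercept + linear covariates
    lin_cols = [np.ones(n)] + [covariate(c) for c in spec.linear_terms]
    lin = np.column_stack(lin_cols)
    blocks.append(lin)
    terms.append(Term("parametric", col, col + lin.shape[1], False, False))
    names += ["Intercept"] + list(spec.linear_terms)
    col += lin.shape[1]
    meta["covariate_means"] = {
        c: float(np.mean(records[c])) for c in spec.linear_terms
    }

    osc = covariate("osc")
    surp = covariate("surprisal")
    meta["osc_range"] = (float(osc.min()), float(osc.max()))
    meta["surprisal_range"] = (float(surp.min()), float(surp.max()))
    meta["rug"] = np.column_stack([osc, surp])

    if spec.interaction_form == "tensor":
        for name, x, k in (("osc", osc, spec.k_osc),
                           ("surprisal", surp, spec.k_surprisal)):
            if np.unique(x).size < k:
                raise ValueError(
                    f"covariate {name!r} has fewer than {k} unique values; "
                    "reduce the marginal basis size"
                )
        B1, knots1 = bspline_basis(osc, spec.k_osc, osc.min(), osc.max())
        B2, knots2 = bspline_basis(
            surp, spec.k_surprisal, surp.min(), surp.max()
        )
        T = _row_kronecker(B1, B2)
        # sum-to-zero constraint: project out the column-mean direction
        cmean = T.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(cmean.T, mode="complete")
        Z = q[:, 1:]
        Xt = T @ Z
        S1 = np.kron(
            difference_penalty(spec.k_osc, spec.penalty_order),
            np.eye(spec.k_surprisal),
        )
        S2 = np.kron(
            np.eye(spec.k_osc),
            difference_penalty(spec.k_surprisal, spec.penalty_order),
        )
        term = Term(
            "te(osc,surprisal)",
            col,
            col + Xt.shape[1],
            True,
            True,
            [Z.T @ S1 @ Z, Z.T @ S2 @ Z],
        )
        blocks.append(Xt)
        terms.append(term)
        names += [f"te.{i + 1}" for i in range(Xt.shape[1])]
        col += Xt.shape[1]
        meta["tensor"] = {"knots_osc": knots1, "knots_surprisal": knots2,
                          "Z": Z, "k_osc": spec.k_osc,
                          "k_surprisal": spec.k_surprisal}
    else:
        Xi = np.column_stack([osc, surp, osc * surp])
        blocks.append(Xi)
        terms.append(Term("linear_interaction", col, col + 3, False, False))
        names += ["osc", "surprisal", "osc_x_surprisal"]
        col += 3

    if spec.random_effects:
        for key, label in (("subject_id", "s(subject)"), ("word_type", "s(word)")):
            if key not in records.columns:
                raise ValueError(f"random effects requested but {key!r} missing")
            levels, codes = np.unique(records[key].astype(str), return_inverse=True)
            Zr = np.zeros((n, levels.size))
            Zr[np.arange(n), codes] = 1.0
            blocks.append(Zr)
            terms.append(
                Term(label, col, col + levels.size, True, True,
                     [np.eye(levels.size)])
            )
            names += [f"{label}.{lv}" for lv in levels]
            col += levels.size
            meta[f"levels_{key}"] = list(levels)

    X = np.column_stack(blocks)
    return Design(X=X, terms=terms, column_names=names, meta=meta)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Summary of one penalized fit, mirroring a mixed-GAM summary table."""

    parametric: pd.DataFrame  # estimate, se, t, p per unpenalized coefficient
    smooth: pd.DataFrame  # edf, ref_df, F, p per penalized term
    deviance_explained: float
    n: int
    edf_total: float
    sigma2: float
    rss: float
    gcv: float
    lambdas: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "parametric": self.parametric.round(10).to_dict("records"),
            "smooth": self.smooth.round(10).to_dict("records"),
            "deviance_explained": round(float(self.deviance_explained), 10),
            "n": int(self.n),
            "edf_total": round(float(self.edf_total), 8),
            "sigma2": round(float(self.sigma2), 12),
            "rss": round(float(self.rss), 10),
            "gcv": round(float(self.gcv), 12),
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
        }


@dataclass
class SurfaceGrid:
    """Predicted interaction surface on a rectangular (osc, surprisal) grid."""

    osc: np.ndarray  # (g1,)
    surprisal: np.ndarray  # (g2,)
    fit: np.ndarray  # (g1, g2) predicted log DV
    se: np.ndarray  # (g1, g2)
    extrapolated: np.ndarray  # (g1, g2) bool
    rug: np.ndarray  # (n, 2) training (osc, surprisal)

    def to_frame(self) -> pd.DataFrame:
        o, s = np.meshgrid(self.osc, self.surprisal, indexing="ij")
        return pd.DataFrame(
            {
                "osc": o.ravel(),
                "surprisal": s.ravel(),
                "fit": self.fit.ravel(),
                "se": self.se.ravel(),
                "extrapolated": self.extrapolated.ravel(),
            }
        )


class GAMConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_criterion: float | None = None):
        super().__init__(msg)
        self.last_criterion = last_criterion


class PenalizedGAM(BaseEstimator, RegressorMixin):
    """Penalized additive model for log reading times.

    Scikit-learn style estimator: ``fit(X, y)`` takes a record DataFrame
    (covariate, subject and word columns) and the log-DV vector; fitted
    state lives in trailing-underscore attributes.

    Parameters mirror :class:`ModelSpec`; ``fixed_lambdas`` bypasses GCV
    (scalar applied to all penalties, or a list in penalty order), which is
    how the lambda -> 0 ordinary-least-squares oracle and the
    lambda -> infinity null-space limits are exercised.
    """

    def __init__(
        self,
        interaction_form: str = "tensor",
        linear_terms: tuple[str, ...] = ("length", "log_frequency", "position"),
        k_osc: int = 5,
        k_surprisal: int = 5,
        penalty_order: int = 2,
        random_effects: bool = True,
        smoothing_selection: str = "gcv",
        max_iter: int = 20,
        tolerance: float = 1e-6,
        fixed_lambdas=None,
    ):
        self.interaction_form = interaction_form
        self.linear_terms = linear_terms
        self.k_osc = k_osc
        self.k_surprisal = k_surprisal
        self.penalty_order = penalty_order
        self.random_effects = random_effects
        self.smoothing_selection = smoothing_selection
        self.max_iter = max_iter
        self.tolerance = tolerance
        self.fixed_lambdas = fixed_lambdas

    # -- internal ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            linear_terms=tuple(self.linear_terms),
            interaction_form=self.interaction_form,
            k_osc=self.k_osc,
            k_surprisal=self.k_surprisal,
            penalty_order=self.penalty_order,
            random_effects=self.random_effects,
            smoothing_selection=self.smoothing_selection,
            max_iter=self.max_iter,
            tolerance=self.tolerance,
        )

    def _factor(self, lambdas: np.ndarray):
        A = self._XtX.copy()
        for lam, S in zip(lambdas, self._penalties_full):
            A += lam * S
        try:
            return cho_factor(A, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover
            raise GAMConvergenceError(f"normal equations not PD: {e}")

    def _solve(self, lambdas: np.ndarray, Xty=None, yty=None, need_trace=True):
        Xty = self._Xty if Xty is None else Xty
        yty = self._yty if yty is None else yty
        c = self._factor(lambdas)
        beta = cho_solve(c, Xty)
        if need_trace:
            M = cho_solve(c, self._XtX)
            edf = float(np.trace(M))
        else:
            M, edf = None, float("nan")
        rss = float(yty - 2.0 * beta @ Xty + beta @ (self._XtX @ beta))
        rss = max(rss, 0.0)
        return c, beta, M, edf, rss

    def _gcv(self, lambdas: np.ndarray, Xty=None, yty=None) -> float:
        _, _, _, edf, rss = self._solve(lambdas, Xty, yty)
        n = self._n
        denom = max(n - edf, 1.0)
        return n * rss / denom**2

    def _reml(self, lambdas: np.ndarray, Xty=None, yty=None) -> float:
        """Negative restricted log-likelihood (Gaussian, sigma^2 profiled).

        V = (n - Mp) log sigma2_hat + log|X'X + S| - log|S|_+ with
        sigma2_hat = (RSS + penalty) / (n - Mp); Mp is the dimension of the
        total penalty null space.  Penalties are block-diagonal, so the
        pseudo-determinant is a sum of per-block contributions.
        """
        c, beta, _, _, rss = self._solve(lambdas, Xty, yty, need_trace=False)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        pen = 0.0
        logdet_S = 0.0
        rank_S = 0
        li = 0
        for t in self.design_.terms:
            if not t.penalties:
                continue
            bj = beta[t.start : t.stop]
            S_block = np.zeros((t.size, t.size))
            for S in t.penalties:
                S_block += lambdas[li] * S
                li += 1
            pen += float(bj @ S_block @ bj)
            eig = np.linalg.eigvalsh(S_block)
            tol = max(eig.max(), 0.0) * 1e-10
            pos = eig[eig > tol]
            logdet_S += float(np.sum(np.log(pos)))
            rank_S += pos.size
        p = self.design_.X.shape[1]
        mp = p - rank_S
        df = max(self._n - mp, 1.0)
        sigma2 = max(rss + pen, 1e-300) / df
        return df * np.log(sigma2) + logdet_A - logdet_S

    def _criterion(self, lambdas: np.ndarray, Xty=None, yty=None) -> float:
        if self.smoothing_selection == "reml":
            return self._reml(lambdas, Xty, yty)
        return self._gcv(lambdas, Xty, yty)

    def _select_lambdas(self) -> np.ndarray:
        m = self.design_.penalty_count
        if m == 0:
            return np.zeros(0)
        if self.fixed_lambdas is not None:
            fx = self.fixed_lambdas
            if np.isscalar(fx):
                return np.full(m, float(fx))
            fx = np.asarray(fx, dtype=float)
            if fx.size != m:
                raise ValueError(
                    f"fixed_lambdas has {fx.size} entries, expected {m}"
                )
            return fx
        if self.smoothing_selection not in ("gcv", "reml"):
            raise ValueError(
                f"unknown smoothing selection {self.smoothing_selection!r}"
            )
        loglam = np.zeros(m)
        return self._optimize_lambdas(
            loglam, free_idx=list(range(m)), xatol=0.02
        )

    def _optimize_lambdas(
        self,
        loglam_start: np.ndarray,
        free_idx: list[int],
        Xty=None,
        yty=None,
        xatol: float = 0.02,
        max_sweeps: int | None = None,
    ) -> np.ndarray:
        """Coordinate-wise golden-section descent over log10 lambdas."""
        loglam = np.asarray(loglam_start, dtype=float).copy()
        if not free_idx:
            return 10.0**loglam
        best = self._criterion(10.0**loglam, Xty, yty)
        lo, hi = LOG10_LAMBDA_BOUNDS
        max_sweeps = max_sweeps if max_sweeps is not None else self.max_iter
        for sweep in range(max_sweeps):
            prev = best
            for j in free_idx:
                def obj(l, j=j):
                    trial = loglam.copy()
                    trial[j] = l
                    return self._criterion(10.0**trial, Xty, yty)

                res = minimize_scalar(
                    obj, bounds=(lo, hi), method="bounded",
                    options={"xatol": xatol},
                )
                if res.fun <= best:
                    best = float(res.fun)
                    loglam[j] = float(res.x)
            if prev - best <= self.tolerance * (1.0 + abs(best)):
                return 10.0**loglam
        if max_sweeps < self.max_iter:  # truncated refinement is acceptable
            return 10.0**loglam
        raise GAMConvergenceError(
            f"smoothing-parameter descent did not converge in "
            f"{max_sweeps} sweeps",
            last_criterion=best,
        )

    def _refit_response(self, y: np.ndarray, free_idx: list[int],
                        xatol: float = 0.1, max_sweeps: int = 2):
        """Light refit on a new response over the cached design.

        Re-selects only the smoothing parameters in ``free_idx`` (warm
        started at the fitted values); returns (rss, edf_total, per-term
        edf dict) without touching the fitted state.  Used by the
        bootstrap calibration of the model comparison.
        """
        Xty = self.design_.X.T @ y
        yty = float(y @ y)
        loglam = np.log10(np.maximum(self.lambdas_, 10.0 ** LOG10_LAMBDA_BOUNDS[0]))
        lambdas = self._optimize_lambdas(
            loglam, free_idx, Xty, yty, xatol=xatol, max_sweeps=max_sweeps
        )
        _, _, M, edf, rss = self._solve(lambdas, Xty, yty, need_trace=True)
        diag = np.diag(M)
        term_edf = {
            t.name: float(diag[t.start : t.stop].sum())
            for t in self.design_.terms
        }
        return rss, edf, term_edf

    # -- public API --------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "PenalizedGAM":
        spec = self._spec()
        design = build_design(X, spec)
        yv = np.asarray(y, dtype=float)
        if yv.shape[0] != design.X.shape[0]:
            raise ValueError("X and y have different lengths")
        if not np.all(np.isfinite(yv)):
            raise ValueError("non-finite response values")

        self.design_ = design
        self._n = yv.shape[0]
        self._XtX = design.X.T @ design.X
        self._Xty = design.X.T @ yv
        self._yty = float(yv @ yv)
        self._penalties_full = design.full_penalties()

        lambdas = self._select_lambdas()
        c, beta, M, edf, rss = self._solve(lambdas)

        n, p = self._n, design.X.shape[1]
        sigma2 = rss / max(n - edf, 1.0)
        Ainv = cho_solve(c, np.eye(p))
        Vb = sigma2 * Ainv

        self.coef_ = beta
        self.Vb_ = Vb
        self.lambdas_ = lambdas
        self.edf_total_ = edf
        self.sigma2_ = sigma2
        self.rss_ = rss
        self.fitted_ = design.X @ beta
        self.residuals_ = yv - self.fitted_
        self._y = yv
        tss = float(np.sum((yv - yv.mean()) ** 2))
        self.deviance_explained_ = 1.0 - rss / tss if tss > 0 else 0.0
        denom = max(n - edf, 1.0)
        self.gcv_ = n * rss / denom**2

        # per-term edf and summary tables
        diag = np.diag(M)
        lam_names: list[str] = []
        lam_i = 0
        param_rows = []
        smooth_rows = []
        self.edf_ = {}
        for t in design.terms:
            sl = slice(t.start, t.stop)
            t_edf = float(diag[sl].sum())
            self.edf_[t.name] = t_edf
            for pi in range(len(t.penalties)):
                lam_names.append(f"{t.name}[{pi}]")
            lam_i += len(t.penalties)
            if not t.penalized:
                for j in range(t.start, t.stop):
                    se = float(np.sqrt(max(Vb[j, j], 0.0)))
                    est = float(beta[j])
                    tval = est / se if se > 0 else np.nan
                    pval = (
                        2.0 * stats.t.sf(abs(tval), df=max(n - edf, 1.0))
                        if np.isfinite(tval)
                        else np.nan
                    )
                    param_rows.append(
                        {
                            "term": design.column_names[j],
                            "estimate": est,
                            "se": se,
                            "t": tval,
                            "p": pval,
                        }
                    )
            else:
                bj = beta[sl]
                Vj = Vb[sl, sl]
                Vinv = np.linalg.pinv(Vj, rcond=1e-10)
                df1 = max(t_edf, 1e-8)
                F = float(bj @ Vinv @ bj) / df1
                pval = float(stats.f.sf(F, df1, max(n - edf, 1.0)))
                smooth_rows.append(
                    {
                        "term": t.name,
                        "edf": t_edf,
                        "ref_df": t.size,
                        "F": F,
                        "p": pval,
                    }
                )
        self.fit_result_ = FitResult(
            parametric=pd.DataFrame(
                param_rows, columns=["term", "estimate", "se", "t", "p"]
            ),
            smooth=pd.DataFrame(
                smooth_rows, columns=["term", "edf", "ref_df", "F", "p"]
            ),
            deviance_explained=self.deviance_explained_,
            n=n,
            edf_total=edf,
            sigma2=sigma2,
            rss=rss,
            gcv=self.gcv_,
            lambdas=dict(zip(lam_names, lambdas)),
        )
        return self

    def _design_rows(self, X: pd.DataFrame) -> np.ndarray:
        """Model-matrix rows for new data under the fitted layout."""
        design = self.design_
        n = len(X)
        cols = np.zeros((n, design.X.shape[1]))
        for t in design.terms:
            if t.name == "parametric":
                block = [np.ones(n)] + [
                    np.asarray(X[c], dtype=float) for c in self.linear_terms
                ]
                cols[:, t.start : t.stop] = np.column_stack(block)
            elif t.name == "te(osc,surprisal)":
                meta = design.meta["tensor"]
                B1 = BSpline.design_matrix(
                    np.asarray(X["osc"], dtype=float),
                    meta["knots_osc"], 3, extrapolate=True,
                ).toarray()
                B2 = BSpline.design_matrix(
                    np.asarray(X["surprisal"], dtype=float),
                    meta["knots_surprisal"], 3, extrapolate=True,
                ).toarray()
                cols[:, t.start : t.stop] = _row_kronecker(B1, B2) @ meta["Z"]
            elif t.name == "linear_interaction":
                o = np.asarray(X["osc"], dtype=float)
                s = np.asarray(X["surprisal"], dtype=float)
                cols[:, t.start : t.stop] = np.column_stack([o, s, o * s])
            else:  # random effects: unknown levels predict at zero
                key = "subject_id" if t.name == "s(subject)" else "word_type"
                if key in X.columns:
                    levels = design.meta[f"levels_{key}"]
                    index = {lv: i for i, lv in enumerate(levels)}
                    for i, v in enumerate(X[key].astype(str)):
                        j = index.get(v)
                        if j is not None:
                            cols[i, t.start + j] = 1.0
        return cols

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        return self._design_rows(X) @ self.coef_

    def predict_surface(
        self,
        n_grid: int = 30,
        osc_grid: np.ndarray | None = None,
        surprisal_grid: np.ndarray | None = None,
    ) -> SurfaceGrid:
        """Predicted log DV over an (osc, surprisal) grid.

        Linear covariates are held at their training means and random
        effects at zero; grid points outside the observed covariate ranges
        are flagged as extrapolated.
        """
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        meta = self.design_.meta
        o_lo, o_hi = meta["osc_range"]
        s_lo, s_hi = meta["surprisal_range"]
        og = (
            np.asarray(osc_grid, dtype=float)
            if osc_grid is not None
            else np.linspace(o_lo, o_hi, n_grid)
        )
        sg = (
            np.asarray(surprisal_grid, dtype=float)
            if surprisal_grid is not None
            else np.linspace(s_lo, s_hi, n_grid)
        )
        oo, ss = np.meshgrid(og, sg, indexing="ij")
        grid = pd.DataFrame(
            {
                "osc": oo.ravel(),
                "surprisal": ss.ravel(),
                **{
                    c: meta["covariate_means"][c]
                    for c in self.linear_terms
                },
            }
        )
        rows = self._design_rows(grid)
        fit = rows @ self.coef_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", rows, self.Vb_, rows), 0.0))
        extrap = (
            (grid["osc"] < o_lo)
            | (grid["osc"] > o_hi)
            | (grid["surprisal"] < s_lo)
            | (grid["surprisal"] > s_hi)
        ).to_numpy()
        shape = (og.size, sg.size)
        return SurfaceGrid(
            osc=og,
            surprisal=sg,
            fit=fit.reshape(shape),
            se=se.reshape(shape),
            extrapolated=extrap.reshape(shape),
            rug=meta["rug"],
        )

    @property
    def interaction_edf_(self) -> float:
        """Effective degrees of freedom of the interaction term."""
        if self.interaction_form == "tensor":
            return self.edf_["te(osc,surprisal)"]
        return 3.0  # unpenalized bilinear columns

    def summary(self) -> dict:
        return self.fit_result_.to_dict()


def fit_penalized(
    records: pd.DataFrame, spec: ModelSpec | None = None, **kwargs
) -> PenalizedGAM:
    """Fit the model on an assembled record table (log DV in ``log_dv``)."""
    spec = spec or ModelSpec(**kwargs)
    model = PenalizedGAM(
        interaction_form=spec.interaction_form,
        linear_terms=spec.linear_terms,
        k_osc=spec.k_osc,
        k_surprisal=spec.k_surprisal,
        penalty_order=spec.penalty_order,
        random_effects=spec.random_effects,
        smoothing_selection=spec.smoothing_selection,
        max_iter=spec.max_iter,
        tolerance=spec.tolerance,
    )
    return model.fit(records, records[spec.dv_name])


# ---------------------------------------------------------------------------
# model comparison and criticism


@dataclass
class ComparisonResult:
    """Approximate F comparison of tensor vs linear interaction forms."""

    F: float
    df_num: float
    df_den: float
    p: float
    preferred_form: str
    inconclusive: bool
    tensor_fit: PenalizedGAM
    linear_fit: PenalizedGAM
    calibration: str = "bootstrap"

    def to_dict(self) -> dict:
        return {
            "F": float(self.F),
            "df_num": float(self.df_num),
            "df_den": float(self.df_den),
            "p": float(self.p),
            "preferred_form": self.preferred_form,
            "inconclusive": bool(self.inconclusive),
            "calibration": self.calibration,
        }


def compare_forms(
    records: pd.DataFrame,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
    edf_margin: float = 1.0,
    null_calibration: str = "bootstrap",
    n_boot: int = 19,
    random_state: int = 0,
    **kwargs,
) -> ComparisonResult:
    """Is the nonlinear interaction surface justified over a bilinear one?

    Both forms are fitted to the same records; the gain in fit is summarised
    by the statistic

        F = [(RSS_lin - RSS_te) / (edf_te - edf_lin)] / [RSS_te / (n - edf_te_total)]

    So that the comparison isolates the interaction term, the nuisance
    smoothing is held fixed: the random-effect smoothing parameters chosen
    for the tensor model are reused when fitting the bilinear form.  (If the
    linear model re-selected them freely, the word intercepts — one level
    per word type, with consistency a word-level covariate — could absorb
    the very surface under test and the residual comparison would be blind
    to it.)

    Because the tensor smoothing parameters are estimated from the same data,
    referring F to a nominal F distribution is anti-conservative.  The
    default reference is therefore a parametric bootstrap (Monte Carlo
    test): ``n_boot`` responses are simulated from the fitted *linear*
    model, the statistic is recomputed for each with the tensor smoothing
    re-selected, and p = (1 + #{F* >= F}) / (n_boot + 1).  With the default
    ``n_boot = 19`` the decision at alpha = 0.05 is an exact-size Monte
    Carlo test.  ``null_calibration="f"`` gives the plain (approximate) F
    reference instead.

    When the tensor term's edf does not exceed the bilinear term's by at
    least ``edf_margin`` (default one full degree of freedom — below that
    the smoother has effectively collapsed onto its bilinear null space and
    carries no usable evidence of nonlinearity), the comparison is flagged
    inconclusive and the simpler form is preferred.  Ties at ``p >= alpha``
    also prefer the linear form.
    """
    spec = spec or ModelSpec(**kwargs)
    te_spec = ModelSpec(**{**spec.__dict__, "interaction_form": "tensor"})
    lin_spec = ModelSpec(**{**spec.__dict__, "interaction_form": "linear"})
    te = fit_penalized(records, te_spec)
    lin_model = PenalizedGAM(
        interaction_form="linear",
        linear_terms=lin_spec.linear_terms,
        k_osc=lin_spec.k_osc,
        k_surprisal=lin_spec.k_surprisal,
        penalty_order=lin_spec.penalty_order,
        random_effects=lin_spec.random_effects,
        smoothing_selection=lin_spec.smoothing_selection,
        max_iter=lin_spec.max_iter,
        tolerance=lin_spec.tolerance,
        # the tensor term contributes the first two penalties; the remaining
        # ones (random effects) carry over to the bilinear form
        fixed_lambdas=list(te.lambdas_[2:]) if lin_spec.random_effects else None,
    )
    lin = lin_model.fit(records, records[lin_spec.dv_name])

    n = te.fit_result_.n
    df_num = te.interaction_edf_ - lin.interaction_edf_
    df_den = max(n - te.edf_total_, 1.0)
    if df_num <= edf_margin:
        return ComparisonResult(
            F=0.0, df_num=df_num, df_den=df_den, p=1.0,
            preferred_form="linear", inconclusive=True,
            tensor_fit=te, linear_fit=lin, calibration=null_calibration,
        )
    F = max(lin.rss_ - te.rss_, 0.0) / df_num / (te.rss_ / df_den)

    if null_calibration == "f":
        p = float(stats.f.sf(F, df_num, df_den))
    elif null_calibration == "bootstrap":
        # indices of the tensor marginal penalties in the tensor design
        free_idx = [0, 1]
        rng = np.random.default_rng(random_state)
        sd = float(np.sqrt(lin.sigma2_))
        # Null mean: the linear model's *parametric* part only.  Random
        # effects are redrawn iid per bootstrap with the variance components
        # implied by the selected ridge parameters (sigma_b^2 = sigma^2 /
        # lambda_b); reusing the fitted BLUPs instead would leak any surface
        # structure they absorbed into the null reference.
        fixed_mean = np.zeros(n)
        re_blocks: list[tuple[np.ndarray, float]] = []
        lam_i = 0
        for t in lin.design_.terms:
            block = lin.design_.X[:, t.start : t.stop]
            if t.penalized:
                lam = max(float(lin.lambdas_[lam_i]), 1e-8)
                re_blocks.append((block, float(np.sqrt(lin.sigma2_ / lam))))
                lam_i += len(t.penalties)
            else:
                fixed_mean += block @ lin.coef_[t.start : t.stop]
        # The Monte Carlo statistic is the nominal F-distribution p-value,
        # which puts replicates with different selected edf on one scale;
        # the simulation then supplies its true null distribution.
        p_nominal = float(stats.f.sf(F, df_num, df_den))
        exceed = 0
        te_name = "te(osc,surprisal)"
        for _ in range(n_boot):
            ystar = fixed_mean + rng.normal(0.0, sd, size=n)
            for block, sd_b in re_blocks:
                ystar += block @ rng.normal(0.0, sd_b, size=block.shape[1])
            rss_t, edf_t, term_t = te._refit_response(ystar, free_idx)
            rss_l, _, _ = lin._refit_response(ystar, [])
            dfn = term_t[te_name] - 3.0
            if dfn <= edf_margin:
                pb = 1.0
            else:
                Fb = max(rss_l - rss_t, 0.0) / dfn / (
                    rss_t / max(n - edf_t, 1.0)
                )
                pb = float(stats.f.sf(Fb, dfn, max(n - edf_t, 1.0)))
            exceed += pb <= p_nominal
        p = (1.0 + exceed) / (n_boot + 1.0)
    else:
        raise ValueError(f"unknown null calibration {null_calibration!r}")
    preferred = "tensor" if p <= alpha else "linear"
    return ComparisonResult(
        F=float(F), df_num=float(df_num), df_den=float(df_den), p=float(p),
        preferred_form=preferred, inconclusive=False,
        tensor_fit=te, linear_fit=lin, calibration=null_calibration,
    )


def model_criticism(
    records: pd.DataFrame,
    model: PenalizedGAM | None = None,
    spec: ModelSpec | None = None,
    threshold: float = 2.5,
) -> tuple[pd.DataFrame, PenalizedGAM, int]:
    """Trim deviant residuals and refit.

    Records whose standardized residual (residual / fitted residual SD)
    exceeds ``threshold`` in absolute value are removed and the identical
    specification is refitted.  Removing more than half the data is treated
    as a pathological fit and raises.
    """
    spec = spec or ModelSpec()
    if model is None:
        model = fit_penalized(records, spec)
    sd = float(np.sqrt(model.sigma2_))
    std_resid = model.residuals_ / sd if sd > 0 else model.residuals_
    keep = np.abs(std_resid) <= threshold
    removed = int((~keep).sum())
    if removed > 0.5 * len(records):
        raise RuntimeError(
            f"model criticism would remove {removed}/{len(records)} records; "
            "pathological fit"
        )
    trimmed = records.iloc[np.flatnonzero(keep)].reset_index(drop=True)
    refit = fit_penalized(trimmed, spec) if removed else model
    return trimmed, refit, removed
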