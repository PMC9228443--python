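"""Response-surface regression on Box-Behnken data, with Type-III ANOVA.

The separation factor and solute flux measured over the design are fitted
by ordinary least squares to first- or second-order polynomials in the
*coded* factors

    Y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j .

Because the coded Box-Behnken columns are orthogonal for linear and
interaction terms, each such coefficient equals half the difference of the
response means at the +1 and -1 levels — a useful closed-form cross-check.

An actual-unit view of any fitted polynomial is obtained by exact algebraic
re-expansion of the coded polynomial (never by refitting), so predictions
are identical in either unit system.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .design import DesignTable, FactorLevels

__all__ = ["ResponseSurfaceRegressor", "anova", "fit_rsm", "term_names"]

_LINEAR_TERMS = ("x1", "x2", "x3")
_INTERACTION_TERMS = ("x1:x2", "x1:x3", "x2:x3")
_QUADRATIC_TERMS = ("x1^2", "x2^2", "x3^2")


def term_names(form: str, drop_terms: Iterable[str] = ()) -> list[str]:
    """Model terms (after the intercept) for a given model form."""
    if form == "linear":
        terms = list(_LINEAR_TERMS)
    elif form in ("quadratic", "quadratic_reduced"):
        terms = list(_LINEAR_TERMS) + list(_INTERACTION_TERMS) + list(_QUADRATIC_TERMS)
    else:
        raise ValueError(f"unknown model form {form!r}")
    drop = {_canon(t) for t in drop_terms}
    unknown = drop - set(terms)
    if unknown:
        raise ValueError(f"cannot drop unknown terms: {sorted(unknown)}")
    return [t for t in terms if t not in drop]


def _canon(term: str) -> str:
    """Normalize user spellings like 'X1X2', 'x1*x2' to 'x1:x2'."""
    t = term.lower().replace(" ", "").replace("*", "").replace(":", "").replace("_", "")
    if t in ("x1x2", "x2x1"):
        return "x1:x2"
    if t in ("x1x3", "x3x1"):
        return "x1:x3"
    if t in ("x2x3", "x3x2"):
        return "x2:x3"
    if t in ("x1^2", "x12", "x11"):
        return "x1^2"
    if t in ("x2^2", "x22"):
        return "x2^2"
    if t in ("x3^2", "x32", "x33"):
        return "x3^2"
    if t in ("x1", "x2", "x3"):
        return t
    raise ValueError(f"unrecognized term {term!r}")


def _basis(coded: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    x1, x2, x3 = coded[:, 0], coded[:, 1], coded[:, 2]
    col = {
        "x1": x1, "x2": x2, "x3": x3,
        "x1:x2": x1 * x2, "x1:x3": x1 * x3, "x2:x3": x2 * x3,
        "x1^2": x1 ** 2, "x2^2": x2 ** 2, "x3^2": x3 ** 2,
    }
    return np.column_stack([np.ones_like(x1)] + [col[t] for t in terms])


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Polynomial response-surface model fitted by OLS in coded units.

    Parameters
    ----------
    form : {'linear', 'quadratic', 'quadratic_reduced'}
        'linear' fits main effects only; 'quadratic' the full ten-term
        second-order polynomial; 'quadratic_reduced' requires
        ``drop_terms`` and refits without those terms (coefficients are
        re-estimated, not zeroed).
    drop_terms : iterable of str
        Terms excluded from the basis, e.g. ``('x1:x2', 'x2:x3')``.
    levels : FactorLevels or None
        Coding map.  When given, ``X`` passed to :meth:`fit` and
        :meth:`predict` is in actual units (°C, bar, kg m^-3); when None,
        ``X`` is taken to be already coded.

    Attributes
    ----------
    terms_ : list of str
        Fitted basis terms after the intercept.
    coef_coded_ : dict
        Coefficients keyed by term ('const', 'x1', ..., 'x3^2').
    coef_actual_ : dict
        Exact re-expansion of the coded polynomial in actual units
        (present only when ``levels`` is given).
    r2_, r2_adj_ : float
        Coefficient of determination and its adjusted version (NaN when
        the response is constant).
    results_ : statsmodels RegressionResults
        Full OLS diagnostics.
    """

    def __init__(self, form: str = "quadratic", drop_terms: Iterable[str] = (),
                 levels: FactorLevels | None = None):
        self.form = form
        self.drop_terms = drop_terms
        self.levels = levels

    def _to_coded(self, X: np.ndarray) -> np.ndarray:
        return self.levels.code(X) if self.levels is not None else X

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        if X.shape[1] != 3:
            raise ValueError("expected exactly three process factors")
        if self.form == "quadratic_reduced" and not list(self.drop_terms):
            raise ValueError("'quadratic_reduced' requires non-empty drop_terms")
        self.terms_ = term_names(self.form, self.drop_terms)
        coded = self._to_coded(X)
        design = _basis(coded, self.terms_)
        if len(y) <= design.shape[1]:
            raise ValueError("need more runs than model parameters")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design for the requested model form")
        res = sm.OLS(y, design).fit()
        self.results_ = res
        self.coef_ = np.asarray(res.params)
        self.coef_coded_ = dict(zip(["const", *self.terms_], self.coef_))
        if self.levels is not None:
            self.coef_actual_ = _reexpand_actual(self.coef_coded_, self.levels)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0.0:
            self.r2_ = np.nan
            self.r2_adj_ = np.nan
        else:
            self.r2_ = float(res.rsquared)
            self.r2_adj_ = float(res.rsquared_adj)
        self.df_resid_ = int(res.df_resid)
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(np.atleast_2d(np.asarray(X, dtype=float)))
        return _basis(self._to_coded(X), self.terms_) @ self.coef_

    def predict_coded(self, coded):
        """Evaluate at coded coordinates regardless of the fitted unit system."""
        check_is_fitted(self, "coef_")
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        return _basis(coded, self.terms_) @ self.coef_


def _reexpand_actual(coef_coded: Mapping[str, float], levels: FactorLevels) -> dict[str, float]:
    """Exactly re-express a coded polynomial in actual units.

    Substitutes x_i = (X_i - c_i) / h_i into each coded monomial and
    collects coefficients on the actual-unit monomial basis
    {1, T, P, C, T:P, T:C, P:C, T^2, P^2, C^2}.
    """
    c = levels.centers
    h = levels.half_ranges
    names = ["T", "P", "C"]
    out: dict[str, float] = {k: 0.0 for k in
                             ["const", "T", "P", "C", "T:P", "T:C", "P:C", "T^2", "P^2", "C^2"]}
    idx = {"x1": 0, "x2": 1, "x3": 2}
    for term, b in coef_coded.items():
        if term == "const":
            out["const"] += b
        elif term in idx:
            i = idx[term]
            out[names[i]] += b / h[i]
            out["const"] += -b * c[i] / h[i]
        elif ":" in term:
            ti, tj = term.split(":")
            i, j = idx[ti], idx[tj]
            scale = b / (h[i] * h[j])
            out[f"{names[i]}:{names[j]}"] += scale
            out[names[i]] += -scale * c[j]
            out[names[j]] += -scale * c[i]
            out["const"] += scale * c[i] * c[j]
        elif term.endswith("^2"):
            i = idx[term[:-2]]
            scale = b / h[i] ** 2
            out[f"{names[i]}^2"] += scale
            out[names[i]] += -2.0 * scale * c[i]
            out["const"] += scale * c[i] ** 2
        else:  # pragma: no cover - guarded by term_names
            raise ValueError(f"unknown term {term!r}")
    return out


def fit_rsm(design: DesignTable, response: str, form: str = "quadratic",
            drop_terms: Iterable[str] = ()) -> ResponseSurfaceRegressor:
    """Fit a response surface to a design table's measured response.

    Thin wrapper building a :class:`ResponseSurfaceRegressor` with the
    table's coding map and fitting it on the actual-unit factor columns.
    """
    model = ResponseSurfaceRegressor(form=form, drop_terms=drop_terms, levels=design.levels)
    return model.fit(design.actual, design.response(response))


def anova(design: DesignTable, response: str, form: str = "quadratic",
          drop_terms: Iterable[str] = ()) -> pd.DataFrame:
    """ANOVA table for a response-surface fit (partial, Type-III sums of squares).

    Per-term rows carry the partial sum of squares, degrees of freedom,
    mean square, F against the residual mean square, and p-value.  Center
    replicates provide the pure-error row; lack of fit is the residual
    remainder and is tested against pure error.  The returned frame's
    ``attrs`` carry ``r2`` and ``r2_adj``.
    """
    model = fit_rsm(design, response, form=form, drop_terms=drop_terms)
    y = design.response(response)
    terms = model.terms_
    Xd = _basis(design.coded, terms)
    beta = model.coef_
    resid = y - Xd @ beta
    ss_resid = float(resid @ resid)
    df_resid = len(y) - Xd.shape[1]
    ms_resid = ss_resid / df_resid
    ss_total = float(np.sum((y - y.mean()) ** 2))

    # partial SS of a 1-df term: beta_j^2 / [(X'X)^-1]_jj
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    rows = []
    for j, t in enumerate(terms, start=1):
        ss = beta[j] ** 2 / xtx_inv[j, j]
        f = ss / ms_resid
        rows.append((t, ss, 1, ss, f, float(stats.f.sf(f, 1, df_resid))))

    rows.append(("Residual", ss_resid, df_resid, ms_resid, np.nan, np.nan))

    center = design.center_mask()
    n_center = int(center.sum())
    if n_center >= 2:
        yc = y[center]
        ss_pe = float(np.sum((yc - yc.mean()) ** 2))
        df_pe = n_center - 1
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = np.nan, np.nan
        rows.append(("Lack of Fit", ss_lof, df_lof,
                     ss_lof / df_lof if df_lof else np.nan, f_lof, p_lof))
        rows.append(("Pure error", ss_pe, df_pe, ss_pe / df_pe, np.nan, np.nan))
    else:
        import warnings

        warnings.warn("no center replicates: pure-error and lack-of-fit rows omitted",
                      stacklevel=2)

    rows.append(("Total", ss_total, len(y) - 1, np.nan, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "ss", "df", "ms", "F", "p"])
    table.attrs["r2"] = 1.0 - ss_resid / ss_total if ss_total > 0 else np.nan
    table.attrs["r2_adj"] = (
        1.0 - (ss_resid / df_resid) / (ss_total / (len(y) - 1)) if ss_total > 0 else np.nan
    )
    table.attrs["response"] = response
    table.attrs["form"] = form
    return table
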