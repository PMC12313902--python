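"""Single-descriptor polynomial QSPR models.

The modelling object follows the statsmodels convention: build a
:class:`PolynomialQSPR` from data, call :meth:`~PolynomialQSPR.fit` to
obtain a :class:`QSPRResults` carrying coefficients, the statistics panel
(R, R^2, residual standard error, F statistic, p-value) and ``summary()``.

Model:  y = b0 + b1*x (+ b2*x^2 + b3*x^3) + eps,  fitted by ordinary least
squares on the raw monomial design.  The statistics panel is the classical
OLS one:

* R^2 = 1 - RSS/TSS, R = +sqrt(R^2) (reported as a magnitude),
* S_E = sqrt(RSS/(n-k-1))   (residual standard error, k regressors),
* F   = (R^2/k) / ((1-R^2)/(n-k-1)),  p = upper tail of F(k, n-k-1).

Raw monomials (not orthogonal polynomials) keep the printed coefficients
directly interpretable; the design condition number is logged for
ill-scaled regressors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PROPERTY_NAMES, DrugRecord
from .indices import INDEX_NAMES

logger = logging.getLogger(__name__)

__all__ = ["PolynomialQSPR", "QSPRResults", "fit_polynomial", "qspr_table",
           "prediction_table"]

_RANK_TOL = 1e-10  # relative singular-value cutoff for rank checks


class DegenerateDataError(ValueError):
    """Design rank-deficient or response constant: statistics undefined."""


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, N=degree + 1, increasing=True)


class PolynomialQSPR:
    """Polynomial regression of one property on one topological index.

    Parameters
    ----------
    y, x : array-like, same length n
        Response (property) and regressor (descriptor) values.
    degree : {1, 3}
        Linear or cubic model.
    regressor_name, response_name : str, optional
        Labels carried into results and summaries.
    """

    def __init__(self, y, x, degree: int = 1, regressor_name: str = "TI",
                 response_name: str = "y"):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        if degree not in (1, 3):
            raise ValueError("degree must be 1 (linear) or 3 (cubic)")
        self.degree = degree
        self.regressor_name = regressor_name
        self.response_name = response_name
        n, k = len(self.y), degree
        if self.x.shape != self.y.shape or self.y.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise ValueError("x and y must be finite")
        if n <= k + 1:
            raise DegenerateDataError(
                f"need more than {k + 1} samples for a degree-{k} fit, got {n}")
        if len(np.unique(self.x)) < k + 1:
            raise DegenerateDataError(
                f"need at least {k + 1} distinct x values for degree {k}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str,
                       regressor: str, degree: int = 1) -> "PolynomialQSPR":
        return cls(frame[response].to_numpy(), frame[regressor].to_numpy(),
                   degree=degree, regressor_name=regressor,
                   response_name=response)

    def fit(self) -> "QSPRResults":
        X = _design(self.x, self.degree)
        # rank check on the unit-scaled regressor: scaling x multiplies the
        # design columns by constants, so deficiency is unaffected, while a
        # legitimately wide-ranged x no longer masquerades as degenerate
        scale = np.max(np.abs(self.x))
        Xs = _design(self.x / scale, self.degree) if scale > 0 else X
        svs = np.linalg.svd(Xs, compute_uv=False)
        if svs[-1] <= _RANK_TOL * len(self.y) * svs[0]:
            raise DegenerateDataError("rank-deficient design (constant or "
                                      "nearly collinear regressor powers)")
        sv = np.linalg.svd(X, compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        if cond > 1e8:
            logger.debug("ill-conditioned design for %s~%s (cond=%.3g)",
                         self.response_name, self.regressor_name, cond)
        beta, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        if tss <= 0.0:
            raise DegenerateDataError("constant response: R^2 undefined")
        n, k = len(self.y), self.degree
        r2 = 1.0 - rss / tss
        dof = n - k - 1
        se = float(np.sqrt(rss / dof))
        # F from the R^2 decomposition; equals MSR/MSE for OLS with intercept
        denom = 1.0 - r2
        with np.errstate(over="ignore", divide="ignore"):
            fstat = np.inf if denom <= 0 else (r2 / k) / (denom / dof)
        pval = float(stats.f.sf(fstat, k, dof))
        return QSPRResults(model=self, params=beta, rsquared=r2,
                           resid=resid, se_resid=se, fvalue=float(fstat),
                           f_pvalue=pval, condition_number=float(cond))


@dataclass(frozen=True)
class QSPRResults:
    """Fitted polynomial QSPR model with its statistics panel."""

    model: PolynomialQSPR
    params: np.ndarray          # b0..b_degree, ascending powers
    rsquared: float
    resid: np.ndarray
    se_resid: float             # sqrt(RSS/(n-k-1))
    fvalue: float
    f_pvalue: float
    condition_number: float = field(repr=False, default=np.nan)

    @property
    def r(self) -> float:
        """Correlation magnitude, +sqrt(R^2)."""
        return float(np.sqrt(max(self.rsquared, 0.0)))

    @property
    def nobs(self) -> int:
        return len(self.model.y)

    def predict(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return _design(x, self.model.degree) @ self.params

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.x)

    def equation(self, digits: int = 4) -> str:
        m = self.model
        parts = [f"{self.params[0]:.{digits}f}"]
        for p, b in enumerate(self.params[1:], start=1):
            pw = f"({m.regressor_name})" + ("" if p == 1 else f"^{p}")
            parts.append(f"{'+' if b >= 0 else '-'} {abs(b):.{digits}f}{pw}")
        return f"{m.response_name} = " + " ".join(parts)

    def summary(self) -> str:
        m = self.model
        form = "linear" if m.degree == 1 else "cubic"
        lines = [
            f"Polynomial QSPR ({form}): {m.response_name} ~ {m.regressor_name}",
            f"  n = {self.nobs}",
            f"  {self.equation()}",
            f"  R = {self.r:.3f}   R^2 = {self.rsquared:.3f}   "
            f"S_E = {self.se_resid:.3f}",
            f"  F({m.degree}, {self.nobs - m.degree - 1}) = {self.fvalue:.3f}"
            f"   p = {self.f_pvalue:.3f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.response_name,
            "regressor": self.model.regressor_name,
            "form": "linear" if self.model.degree == 1 else "cubic",
            "coefficients": [float(b) for b in self.params],
            "n": self.nobs,
            "R": self.r,
            "R2": self.rsquared,
            "S_E": self.se_resid,
            "F": self.fvalue,
            "p": self.f_pvalue,
        }


def fit_polynomial(x, y, degree: int = 1, regressor_name: str = "TI",
                   response_name: str = "y") -> QSPRResults:
    """Functional shorthand for ``PolynomialQSPR(y, x, degree).fit()``."""
    return PolynomialQSPR(y, x, degree=degree, regressor_name=regressor_name,
                          response_name=response_name).fit()


def _records_frame(records: list[DrugRecord]) -> pd.DataFrame:
    rows = {}
    for rec in records:
        row = dict(rec.properties)
        row.update(rec.descriptors.as_dict())
        rows[rec.name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def qspr_table(records: list[DrugRecord], index_name: str,
               properties=PROPERTY_NAMES) -> pd.DataFrame:
    """Statistics table for one descriptor: 7 properties x {linear, cubic}.

    Mirrors the classical QSPR report layout: one row per property and
    model form, with the fitted equation and the full statistics panel.
    """
    if index_name not in INDEX_NAMES:
        raise KeyError(f"unknown index {index_name!r}")
    if len(records) < 5:
        raise DegenerateDataError("need at least 5 records for a QSPR table")
    frame = _records_frame(records)
    rows = []
    for prop in properties:
        for degree, form in ((1, "linear"), (3, "cubic")):
            res = PolynomialQSPR.from_dataframe(frame, prop, index_name,
                                                degree=degree).fit()
            rows.append({"property": prop, "model": form,
                         "equation": res.equation(),
                         "R": res.r, "R2": res.rsquared,
                         "S_E": res.se_resid, "F": res.fvalue,
                         "p": res.f_pvalue})
    return pd.DataFrame(rows)


def prediction_table(records: list[DrugRecord], property_name: str,
                     indices=INDEX_NAMES) -> pd.DataFrame:
    """Actual-vs-predicted matrix for one property.

    One row per (index, form), one column per drug, plus a leading
    ``actual`` row; every model is fitted on all records (in-sample, as the
    reference analysis does).
    """
    if property_name not in PROPERTY_NAMES:
        raise KeyError(f"unknown property {property_name!r}")
    frame = _records_frame(records)
    out = {("actual", ""): frame[property_name]}
    for name in indices:
        for degree, form in ((1, "linear"), (3, "cubic")):
            res = PolynomialQSPR.from_dataframe(frame, property_name, name,
                                                degree=degree).fit()
            out[(name, form)] = pd.Series(res.fittedvalues(),
                                          index=frame.index)
    table = pd.DataFrame(out).T
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["index", "model"])
    return table
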