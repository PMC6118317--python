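"""Dose-response curve fitting: 3-parameter logistic and exponential.

The normalized mobility of a worm population versus drug concentration
``x`` is fitted with one of two families by least squares on the linear
concentration axis:

* the three-parameter logistic

      f(x) = A + (1 - A) / (1 + exp(-B (M - x)))

  which falls from an upper plateau of 1 (untreated mobility) to a
  lower asymptote ``A`` with midpoint ``M`` — the EC50 — and slope
  ``B``; and

* the exponential

      f(x) = M exp(-x) + A

  for shallow responses that never resolve both plateaus.  Note this
  family has no concentration-scale parameter: ``x`` enters as-is, so
  the fit inherits the units of the dose axis.

The module follows the Model/Results idiom: construct a
:class:`DoseResponseModel` from (doses, responses), call ``fit()``, and
read estimates, standard errors and diagnostics off the returned
:class:`DoseResponseResults`.  Thin functional wrappers
(:func:`fit_logistic3`, :func:`fit_exponential`) cover the common case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseModel",
    "DoseResponseResults",
    "LogisticFit",
    "ExponentialFit",
    "fit_logistic3",
    "fit_exponential",
    "select_model",
    "ec50",
    "logistic3",
    "exponential",
]


def logistic3(x, A, B, M):
    x = np.asarray(x, dtype=float)
    # guard exp overflow for extreme B*(x - M)
    z = np.clip(-B * (M - x), -700, 700)
    return A + (1.0 - A) / (1.0 + np.exp(z))


def exponential(x, M, A):
    x = np.asarray(x, dtype=float)
    return M * np.exp(-x) + A


@dataclass
class LogisticFit:
    """Parameters of a fitted 3-parameter logistic."""

    A: float
    B: float
    M: float
    rss: float
    converged: bool

    @property
    def ec50(self) -> float:
        return self.M

    def predict(self, x):
        return logistic3(x, self.A, self.B, self.M)


@dataclass
class ExponentialFit:
    """Parameters of a fitted exponential ``M exp(-x) + A``."""

    M: float
    A: float
    rss: float
    converged: bool

    def predict(self, x):
        return exponential(x, self.M, self.A)


class DoseResponseModel:
    """Least-squares dose-response model for one condition.

    Parameters
    ----------
    doses, responses : array-like
        Paired concentrations and control-normalized FMS values.
        Replicates may appear as repeated doses.
    model : {"auto", "logistic3", "exponential"}
        Curve family.  ``auto`` picks by the range of the data (see
        :func:`select_model`); an explicit choice always wins.

    Examples
    --------
    >>> m = DoseResponseModel([0.25, 0.5, 1, 2, 4], [1.0, 0.9, 0.55, 0.2, 0.1])
    >>> res = m.fit()
    >>> round(res.ec50, 2)  # doctest: +SKIP
    1.05
    """

    #: multi-start grid: A floors, B scale factors (divided by dose scale),
    #: M dose quantiles
    _A_STARTS = (0.0, 0.25, 0.5)
    _B_STARTS = (0.5, 2.0, 10.0)
    _M_QUANTILES = (0.25, 0.5, 0.75)

    def __init__(self, doses, responses, model: str = "auto"):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be 1-D and paired")
        keep = np.isfinite(self.doses) & np.isfinite(self.responses)
        self.doses = self.doses[keep]
        self.responses = self.responses[keep]
        if model not in ("auto", "logistic3", "exponential"):
            raise ValueError(f"unknown model {model!r}")
        self.model = model

    @classmethod
    def from_dataframe(
        cls, df, dose_col: str = "dose", response_col: str = "fms_norm", **kw
    ) -> "DoseResponseModel":
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy(), **kw)

    @property
    def n_distinct_doses(self) -> int:
        return np.unique(self.doses).size

    def fit(self) -> "DoseResponseResults":
        model = self.model
        if model == "auto":
            model = select_model(self.doses, self.responses)
        if model == "logistic3":
            fit = self._fit_logistic3()
        else:
            fit = self._fit_exponential()
        return DoseResponseResults(self, model, fit)

    # -- logistic ----------------------------------------------------------
    def _fit_logistic3(self) -> LogisticFit:
        if self.n_distinct_doses < 4:
            raise ValueError(
                "logistic3 fit needs >= 4 distinct doses, got "
                f"{self.n_distinct_doses}"
            )
        x, y = self.doses, self.responses
        lo, hi = x.min(), x.max()
        dose_scale = max(hi - lo, hi, 1e-12)
        # M guard band: within the tested range extended by a decade
        m_lo = max(lo * 0.1, 1e-12) if lo > 0 else 1e-12
        m_hi = hi * 10.0

        def resid(theta):
            A, B, M = theta
            return logistic3(x, A, B, M) - y

        best = None
        for A0 in self._A_STARTS:
            for q in self._M_QUANTILES:
                M0 = float(np.quantile(x, q))
                for b in self._B_STARTS:
                    B0 = b / dose_scale
                    try:
                        sol = least_squares(
                            resid,
                            x0=[A0, B0, np.clip(M0, m_lo, m_hi)],
                            bounds=([0.0, 1e-9, m_lo], [1.0, np.inf, m_hi]),
                            method="trf",
                        )
                    except Exception:
                        continue
                    if not sol.success:
                        continue
                    rss = float(2 * sol.cost)
                    cand = (rss, float(sol.x[1]), sol)
                    # best rss wins; near-ties broken by smaller B
                    if (
                        best is None
                        or rss < best[0] - 1e-12
                        or (abs(rss - best[0]) <= 1e-12 and cand[1] < best[1])
                    ):
                        best = cand
        if best is None:
            return LogisticFit(A=np.nan, B=np.nan, M=np.nan, rss=np.inf, converged=False)
        sol = best[2]
        A, B, M = sol.x
        return LogisticFit(A=float(A), B=float(B), M=float(M), rss=best[0], converged=True)

    # -- exponential -------------------------------------------------------
    def _fit_exponential(self) -> ExponentialFit:
        if self.n_distinct_doses < 3:
            raise ValueError(
                "exponential fit needs >= 3 distinct doses, got "
                f"{self.n_distinct_doses}"
            )
        x, y = self.doses, self.responses
        # linear in (M, A): exact least squares via the normal equations
        design = np.column_stack([np.exp(-x), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        M, A = coef
        rss = float(((design @ coef - y) ** 2).sum())
        return ExponentialFit(M=float(M), A=float(A), rss=rss, converged=True)


class DoseResponseResults:
    """Fit results: parameter estimates, uncertainties and diagnostics."""

    def __init__(self, model: DoseResponseModel, family: str, fit):
        self.model = model
        self.family = family
        self.fit_ = fit
        self.converged = fit.converged
        self.rss = fit.rss
        self.nobs = model.doses.size
        if family == "logistic3":
            self.params = {"A": fit.A, "B": fit.B, "M": fit.M}
        else:
            self.params = {"M": fit.M, "A": fit.A}
        self.bse = self._standard_errors()

    @property
    def ec50(self) -> float:
        """Midpoint concentration of the logistic fit (half-maximal
        transition between the upper plateau 1 and the floor A)."""
        if self.family != "logistic3":
            raise ValueError("EC50 is defined only for the logistic3 family")
        if not self.converged:
            raise ValueError("fit did not converge; EC50 undefined")
        return self.fit_.M

    def predict(self, x):
        return self.fit_.predict(x)

    @property
    def resid(self):
        return self.model.responses - self.predict(self.model.doses)

    def _standard_errors(self) -> dict:
        """Gauss-Newton standard errors from the residual Jacobian."""
        names = list(self.params)
        k = len(names)
        if not self.converged or self.nobs <= k:
            return {n: float("nan") for n in names}
        x = self.model.doses
        eps = 1e-6
        theta = np.array([self.params[n] for n in names])
        J = np.empty((x.size, k))
        for j in range(k):
            t1, t2 = theta.copy(), theta.copy()
            h = eps * max(1.0, abs(theta[j]))
            t1[j] += h
            t2[j] -= h
            J[:, j] = (self._eval(t1, x) - self._eval(t2, x)) / (2 * h)
        dof = self.nobs - k
        s2 = self.rss / dof if dof > 0 else np.nan
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return dict(zip(names, se))

    def _eval(self, theta, x):
        if self.family == "logistic3":
            return logistic3(x, *theta)
        return exponential(x, *theta)

    def summary(self) -> str:
        lines = [
            "Dose-Response Fit",
            "=" * 46,
            f"family:     {self.family}",
            f"nobs:       {self.nobs}",
            f"converged:  {self.converged}",
            f"rss:        {self.rss:.6g}",
            "-" * 46,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<8}{val:>14.6g}{self.bse[name]:>14.6g}")
        if self.family == "logistic3" and self.converged:
            lines.append("-" * 46)
            lines.append(f"EC50 (M):   {self.ec50:.6g}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<DoseResponseResults {self.family}: {p}, rss={self.rss:.4g}>"


def select_model(doses, responses, override: str | None = None) -> str:
    """Pick the curve family from the range of the data.

    ``logistic3`` when the responses resolve both a high plateau
    (max > 0.8) and substantial inhibition (min < 0.5); ``exponential``
    otherwise.  An explicit ``override`` always wins.
    """
    if override is not None:
        if override not in ("logistic3", "exponential"):
            raise ValueError(f"unknown model {override!r}")
        return override
    responses = np.asarray(responses, dtype=float)
    responses = responses[np.isfinite(responses)]
    if responses.size and responses.max() > 0.8 and responses.min() < 0.5:
        return "logistic3"
    return "exponential"


def fit_logistic3(doses, responses) -> LogisticFit:
    """Least-squares 3-parameter logistic fit (multi-start)."""
    return DoseResponseModel(doses, responses, model="logistic3").fit().fit_


def fit_exponential(doses, responses) -> ExponentialFit:
    """Exact least-squares fit of ``M exp(-x) + A`` (linear problem)."""
    return DoseResponseModel(doses, responses, model="exponential").fit().fit_


def ec50(fit: LogisticFit) -> float:
    """EC50 of a converged logistic fit: its midpoint ``M``."""
    if not fit.converged:
        raise ValueError("fit did not converge; EC50 undefined")
    return fit.M
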