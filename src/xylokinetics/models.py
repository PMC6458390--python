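"""Statistical estimation of growth kinetics and allometry.

The package's central estimators follow the model/results idiom: a model
object is built from data, its :meth:`fit` returns a :class:`FitResult`
carrying point estimates, standard errors, goodness of fit, residuals and
a :meth:`FitResult.summary` table.

Three routes estimate the exponential law X(t) = X0 * exp(k t):

``odr``
    Orthogonal distance regression (ODRPACK via :mod:`scipy.odr`):
    minimises orthogonal residuals in the (t, X) plane, each axis scaled
    by its supplied measurement error (unit weights when none are given).
    This is the appropriate estimator when both the sampling day and the
    measured quantity carry error.
``lm``
    Levenberg–Marquardt vertical least squares in linear space.
``ols_log``
    Closed-form ordinary least squares of ln X on t; transparent,
    derivative-free, and used to initialise the iterative routes.

The allometric power law h = c * a**p is fitted in linear space by
Levenberg–Marquardt (optionally with the exponent held fixed, in which
case the prefactor has a closed form), and cross-checked by closed-form
log-log regression whose slope is the scaling exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import odr as scipy_odr
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "ExponentialGrowthModel",
    "PowerLawModel",
    "fit_exponential",
    "fit_power_law",
    "loglog_fit",
    "pearson_r",
    "r_squared",
    "propagate_error",
]

_METHODS = ("odr", "lm", "ols_log")


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics of a single model fit.

    Attributes
    ----------
    estimates : dict
        Named parameter values: ``{"X0": ..., "k": ...}`` for exponential
        fits, ``{"c": ..., "p": ...}`` for power laws.
    std_errors : dict
        One standard error per parameter (same keys).
    r_squared : float
        Coefficient of determination of the fitted response against the
        observed one, computed on the untransformed response for the
        nonlinear routes and on the transformed axes for the closed-form
        log regressions. 1.0 for an exact fit to degenerate
        (zero-variance) data.
    method : str
        ``"odr"``, ``"lm"`` or ``"ols_log"``.
    residuals : ndarray
        observed - fitted, one per data point, on the scale the objective
        was evaluated on.
    converged : bool
        Honest convergence flag of the underlying optimiser.
    """

    estimates: dict
    std_errors: dict
    r_squared: float
    method: str
    residuals: np.ndarray
    converged: bool
    nobs: int = 0
    quantity: str = "value"
    message: str = ""
    _predict: Optional[Callable] = field(default=None, repr=False, compare=False)
    _data: Optional[tuple] = field(default=None, repr=False, compare=False)

    def predict(self, x):
        """Evaluate the fitted model at new abscissae."""
        if self._predict is None:
            raise ValueError("this result does not carry a prediction function")
        return self._predict(np.asarray(x, dtype=float))

    def summary(self) -> str:
        """Plain-text summary table in the model/results idiom."""
        lines = []
        title = f"Fit summary — {self.quantity} ({self.method})"
        lines.append(title)
        lines.append("=" * max(46, len(title)))
        lines.append(
            f"nobs: {self.nobs}    converged: {self.converged}    "
            f"R^2: {self.r_squared:.6g}"
        )
        lines.append("-" * max(46, len(title)))
        lines.append(f"{'param':<10}{'estimate':>16}{'std err':>16}")
        for name, value in self.estimates.items():
            se = self.std_errors.get(name, float("nan"))
            lines.append(f"{name:<10}{value:>16.6g}{se:>16.6g}")
        lines.append("=" * max(46, len(title)))
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready report: ``{quantity, method, estimates, std_errors, r_squared, converged}``."""
        return {
            "quantity": self.quantity,
            "method": self.method,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "r_squared": float(self.r_squared),
            "converged": bool(self.converged),
        }

    def plot(self, ax=None, n_curve: int = 200):
        """Plot the data points and the fitted curve on linear axes."""
        import matplotlib.pyplot as plt

        if self._data is None:
            raise ValueError("this result does not carry its data")
        x, y = self._data
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, y, "ks", label="data")
        if self._predict is not None:
            grid = np.linspace(np.min(x), np.max(x), n_curve)
            ax.plot(grid, self.predict(grid), "k-", label=f"{self.method} fit")
        ax.set_ylabel(self.quantity)
        ax.legend()
        return ax


def _safe_r_squared(observed, predicted):
    """R^2 that tolerates zero-variance data: 1 for a perfect fit, else nan."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if np.isclose(ss_res, 0.0) else float("nan")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# exponential growth model
# ---------------------------------------------------------------------------


class ExponentialGrowthModel:
    """Exponential growth law X(t) = X0 * exp(k t) fitted to a time series.

    Parameters
    ----------
    times : array-like
        Sampling times, days.
    values : array-like
        Measured quantity, any consistent unit.
    value_errors, time_errors : array-like, optional
        One-standard-deviation measurement errors per point, used to
        scale the per-axis residuals under ``odr`` and to weight the
        vertical residuals under ``lm``. ``time_errors`` of exactly zero
        select the vertical (zero-abscissa-error) limit of the orthogonal
        objective.
    quantity : str
        Label carried through to results and reports.
    """

    def __init__(self, times, values, value_errors=None, time_errors=None,
                 quantity: str = "value"):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if self.times.size < 3:
            raise ValueError("need at least 3 points to fit (X0, k)")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("times and values must be finite")
        self.value_errors = None if value_errors is None else np.asarray(value_errors, float)
        self.time_errors = None if time_errors is None else np.asarray(time_errors, float)
        for name, err in (("value_errors", self.value_errors),
                          ("time_errors", self.time_errors)):
            if err is not None:
                if err.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
                if np.any(err < 0):
                    raise ValueError(f"{name} must be >= 0")
        self.quantity = quantity

    @classmethod
    def from_dataframe(cls, df, time_col: str, value_col: str,
                       error_col: Optional[str] = None, **kwargs):
        err = None if error_col is None else df[error_col].to_numpy()
        return cls(df[time_col].to_numpy(), df[value_col].to_numpy(),
                   value_errors=err, **kwargs)

    # -- fitting routes -----------------------------------------------------

    def fit(self, method: str = "odr") -> FitResult:
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
        if method == "ols_log":
            return self._fit_ols_log()
        if method == "lm":
            return self._fit_lm()
        return self._fit_odr()

    def _result(self, X0, k, se_X0, se_k, method, converged, message=""):
        predict = lambda t, X0=X0, k=k: X0 * np.exp(k * t)  # noqa: E731
        fitted = predict(self.times)
        return FitResult(
            estimates={"X0": float(X0), "k": float(k)},
            std_errors={"X0": float(se_X0), "k": float(se_k)},
            r_squared=_safe_r_squared(self.values, fitted),
            method=method,
            residuals=self.values - fitted,
            converged=bool(converged),
            nobs=int(self.times.size),
            quantity=self.quantity,
            message=message,
            _predict=predict,
            _data=(self.times, self.values),
        )

    def _fit_ols_log(self) -> FitResult:
        if np.any(self.values <= 0):
            raise ValueError("ols_log requires strictly positive values")
        res = stats.linregress(self.times, np.log(self.values))
        X0 = math.exp(res.intercept)
        # delta method: se(X0) = X0 * se(intercept)
        se_int = 0.0 if math.isnan(res.intercept_stderr) else res.intercept_stderr
        se_k = 0.0 if math.isnan(res.stderr) else res.stderr
        return self._result(X0, res.slope, X0 * se_int, se_k, "ols_log", True)

    def _initial_guess(self):
        if np.all(self.values > 0):
            r = self._fit_ols_log()
            return r.estimates["X0"], r.estimates["k"]
        # fallback for non-positive data: flat line through the first point
        x0 = self.values[0] if self.values[0] != 0 else 1.0
        return float(x0), 0.0

    def _fit_lm(self) -> FitResult:
        p0 = self._initial_guess()
        sigma = self.value_errors
        if sigma is not None and np.any(sigma == 0):
            sigma = None  # exact points: fall back to unit weights
        try:
            popt, pcov, infodict, mesg, ier = optimize.curve_fit(
                lambda t, X0, k: X0 * np.exp(k * t),
                self.times, self.values, p0=p0, sigma=sigma,
                method="lm", maxfev=2000, full_output=True,
            )
            converged = ier in (1, 2, 3, 4)
        except RuntimeError as exc:  # no convergence within maxfev
            return self._result(p0[0], p0[1], float("nan"), float("nan"),
                                "lm", False, message=str(exc))
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
        return self._result(popt[0], popt[1], perr[0], perr[1], "lm",
                            converged, message="" if converged else mesg)

    def _fit_odr(self) -> FitResult:
        p0 = self._initial_guess()
        model = scipy_odr.Model(lambda beta, t: beta[0] * np.exp(beta[1] * t))
        sx = self.time_errors
        sy = self.value_errors
        vertical = sx is not None and np.all(sx == 0)
        if sy is not None and np.any(sy == 0):
            sy = None
        kwargs = {}
        if not vertical and sx is not None:
            kwargs["sx"] = sx
        if sy is not None:
            kwargs["sy"] = sy
        data = scipy_odr.RealData(self.times, self.values, **kwargs)
        job = scipy_odr.ODR(data, model, beta0=list(p0), maxit=200)
        if vertical:
            # zero abscissa error: the orthogonal objective degenerates to
            # weighted vertical least squares (ODRPACK fit_type 2)
            job.set_job(fit_type=2)
        out = job.run()
        converged = out.info in (1, 2, 3)
        return self._result(out.beta[0], out.beta[1], out.sd_beta[0],
                            out.sd_beta[1], "odr", converged,
                            message="" if converged else "; ".join(out.stopreason))


# ---------------------------------------------------------------------------
# power-law (allometric) model
# ---------------------------------------------------------------------------


class PowerLawModel:
    """Allometric power law y = c * x**p fitted in linear space.

    ``fit(method="lm")`` runs Levenberg–Marquardt on the untransformed
    response, initialised from the closed-form log-log regression. With
    ``fixed_p`` the exponent is held and the prefactor has the closed
    form c = sum(y x^p) / sum(x^(2p)).
    """

    def __init__(self, x, y, quantity: str = "allometry"):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D and equally long")
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("power-law fitting requires x > 0 and y > 0")
        self.quantity = quantity

    @classmethod
    def from_dataframe(cls, df, x_col: str, y_col: str, **kwargs):
        return cls(df[x_col].to_numpy(), df[y_col].to_numpy(), **kwargs)

    def _result(self, c, p, se_c, se_p, method, converged, message=""):
        predict = lambda x, c=c, p=p: c * x ** p  # noqa: E731
        fitted = predict(self.x)
        return FitResult(
            estimates={"c": float(c), "p": float(p)},
            std_errors={"c": float(se_c), "p": float(se_p)},
            r_squared=_safe_r_squared(self.y, fitted),
            method=method,
            residuals=self.y - fitted,
            converged=bool(converged),
            nobs=int(self.x.size),
            quantity=self.quantity,
            message=message,
            _predict=predict,
            _data=(self.x, self.y),
        )

    def fit(self, method: str = "lm", fixed_p: Optional[float] = None) -> FitResult:
        if method != "lm":
            raise ValueError("power-law fitting supports method='lm' only")
        if np.all(self.x == self.x[0]):
            raise ValueError("degenerate x: all abscissae equal, exponent unidentifiable")
        if fixed_p is not None:
            if self.x.size < 2:
                raise ValueError("need at least 2 points with fixed exponent")
            xp = self.x ** fixed_p
            c = float(np.sum(self.y * xp) / np.sum(xp ** 2))
            dof = max(self.x.size - 1, 1)
            s2 = float(np.sum((self.y - c * xp) ** 2)) / dof
            se_c = math.sqrt(s2 / float(np.sum(xp ** 2)))
            return self._result(c, fixed_p, se_c, 0.0, "lm", True)
        if self.x.size < 3:
            raise ValueError("need at least 3 points to fit (c, p)")
        ll = loglog_fit(self.x, self.y)
        p0 = (ll.estimates["c"], ll.estimates["p"])
        try:
            popt, pcov, infodict, mesg, ier = optimize.curve_fit(
                lambda x, c, p: c * x ** p, self.x, self.y, p0=p0,
                method="lm", maxfev=2000, full_output=True,
            )
            converged = ier in (1, 2, 3, 4)
        except RuntimeError as exc:
            return self._result(p0[0], p0[1], float("nan"), float("nan"),
                                "lm", False, message=str(exc))
        with np.errstate(invalid="ignore"):
            perr = np.sqrt(np.diag(pcov))
        return self._result(popt[0], popt[1], perr[0], perr[1], "lm",
                            converged, message="" if converged else mesg)


# ---------------------------------------------------------------------------
# functional wrappers and closed-form statistics
# ---------------------------------------------------------------------------


def fit_exponential(times, values, value_errors=None, time_errors=None,
                    method: str = "odr", quantity: str = "value") -> FitResult:
    """Fit X(t) = X0*exp(k t); see :class:`ExponentialGrowthModel`."""
    return ExponentialGrowthModel(
        times, values, value_errors=value_errors, time_errors=time_errors,
        quantity=quantity,
    ).fit(method=method)


def fit_power_law(x, y, method: str = "lm", fixed_p: Optional[float] = None,
                  quantity: str = "allometry") -> FitResult:
    """Fit y = c*x**p; see :class:`PowerLawModel`."""
    return PowerLawModel(x, y, quantity=quantity).fit(method=method, fixed_p=fixed_p)


def loglog_fit(x, y, quantity: str = "allometry") -> FitResult:
    """Closed-form OLS of ln y on ln x; the slope is the allometric exponent.

    Residuals and R^2 are reported on the (ln x, ln y) axes where the
    regression is linear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with >= 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log regression requires x > 0 and y > 0")
    lx, ly = np.log(x), np.log(y)
    if np.all(lx == lx[0]):
        raise ValueError("degenerate x: all abscissae equal")
    if x.size == 2:
        p = (ly[1] - ly[0]) / (lx[1] - lx[0])
        c = math.exp(ly[0] - p * lx[0])
        se_p = se_c = 0.0
        fitted = np.log(c) + p * lx
    else:
        res = stats.linregress(lx, ly)
        p, c = res.slope, math.exp(res.intercept)
        se_p = 0.0 if math.isnan(res.stderr) else res.stderr
        se_int = 0.0 if math.isnan(res.intercept_stderr) else res.intercept_stderr
        se_c = c * se_int
        fitted = res.intercept + p * lx
    predict = lambda xx, c=c, p=p: c * xx ** p  # noqa: E731
    return FitResult(
        estimates={"c": float(c), "p": float(p)},
        std_errors={"c": float(se_c), "p": float(se_p)},
        r_squared=_safe_r_squared(ly, fitted),
        method="ols_log",
        residuals=ly - fitted,
        converged=True,
        nobs=int(x.size),
        quantity=quantity,
        _predict=predict,
        _data=(x, y),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with >= 2 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1 or observed.size < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, >= 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values have zero variance")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def propagate_error(components: Sequence[tuple], operation: str = "product",
                    scale: float = 1.0) -> tuple:
    """First-order (quadrature) error propagation for simple combinations.

    Parameters
    ----------
    components : sequence of (value, abs_error)
        The measured factors.
    operation : {"product", "quotient", "scaled"}
        ``product`` multiplies all components (times the exact constant
        ``scale``); ``quotient`` divides the first component by the rest;
        ``scaled`` takes a single component times ``scale``. Relative
        errors of the components add in quadrature for products and
        quotients; an exact constant rescales the absolute error only.

    Returns
    -------
    (value, abs_error)
    """
    if operation not in ("product", "quotient", "scaled"):
        raise ValueError(f"unknown operation {operation!r}")
    components = [(float(v), float(e)) for v, e in components]
    for v, e in components:
        if e < 0:
            raise ValueError("absolute errors must be >= 0")
        if v == 0 and e > 0:
            raise ValueError("relative error undefined for zero value with nonzero error")
    if operation == "scaled":
        if len(components) != 1:
            raise ValueError("'scaled' takes exactly one component")
        v, e = components[0]
        return scale * v, abs(scale) * e
    value = scale
    rel_sq = 0.0
    for i, (v, e) in enumerate(components):
        if operation == "quotient" and i > 0:
            if v == 0:
                raise ValueError("division by an exactly zero component")
            value /= v
        else:
            value *= v
        if v != 0:
            rel_sq += (e / v) ** 2
    return value, abs(value) * math.sqrt(rel_sq)
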