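"""Exponential recovery models, statsmodels-style.

The recovery of fluorescence after a bleach is fitted with

    one component:  y(t) = a (1 - exp(-b t))
    two components: y(t) = a (1 - exp(-b t)) + c (1 - exp(-d t)),  b >= d

by unweighted nonlinear least squares on the post-bleach segment (time
origin at the first post-bleach frame, through which the model passes at
0). The half-recovery time is t_1/2 = ln 2 / b for one component and the
numerically solved time at which the curve reaches half its asymptote
(a + c) / 2 for two.

``ExponentialRecoveryModel(times, values).fit()`` returns a
``RecoveryResults`` carrying estimates, standard errors, R^2, AIC and a
``summary()`` table; nested models are compared with
``RecoveryResults.compare_f_test`` or the :func:`select_model` helper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

A_BOUNDS = (1e-12, 2.0)
B_BOUNDS = (1e-3, 1e3)  # spans the measured 10-1000 /s off-rate range and below


class FitError(RuntimeError):
    """Raised when no start converges; carries the best SSE found."""

    def __init__(self, message, best_sse=np.inf):
        super().__init__(message)
        self.best_sse = best_sse


def one_component(t, a, b):
    return a * (1.0 - np.exp(-b * t))


def two_component(t, a, b, c, d):
    return a * (1.0 - np.exp(-b * t)) + c * (1.0 - np.exp(-d * t))


def _initial_rate(times, values, plateau):
    """b0 from a log-linear regression of (plateau - y)."""
    resid = plateau - values
    ok = (resid > 1e-9) & (times > 0)
    if ok.sum() >= 2:
        slope = np.polyfit(times[ok], np.log(resid[ok]), 1)[0]
        if slope < 0:
            return float(np.clip(-slope, *B_BOUNDS))
    # fall back to the reciprocal of the half-range crossing time
    half = 0.5 * plateau
    above = np.flatnonzero(values >= half)
    if len(above) and times[above[0]] > 0:
        return float(np.clip(np.log(2.0) / times[above[0]], *B_BOUNDS))
    return 1.0


class ExponentialRecoveryModel:
    """Recovery model for one bleach experiment (or an averaged curve).

    Parameters
    ----------
    times : array_like
        Post-bleach times in seconds, starting at 0.
    values : array_like
        Background-subtracted, normalized intensities.
    n_components : {1, 2}
    """

    def __init__(self, times, values, n_components: int = 1):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and of equal length")
        if self.times[0] < -1e-12:
            raise ValueError("post-bleach times must start at 0")
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        minimum = 3 if n_components == 1 else 5
        if len(self.times) < minimum:
            raise ValueError(
                f"{n_components}-component fit needs >= {minimum} post-bleach points"
            )
        self.n_components = n_components

    @classmethod
    def from_trace(cls, trace, n_components: int = 1) -> "ExponentialRecoveryModel":
        t, y = trace.postbleach_xy()
        return cls(t, y, n_components=n_components)

    def _starts(self, n_starts, rng):
        plateau = max(float(np.mean(self.values[-max(3, len(self.values) // 5):])), 1e-6)
        a0 = min(plateau, A_BOUNDS[1])
        b0 = _initial_rate(self.times, self.values, plateau)
        if self.n_components == 1:
            base = np.array([a0, b0])
        else:
            base = np.array([0.5 * a0, 5.0 * b0, 0.5 * a0, 0.2 * b0])
        starts = [base]
        for _ in range(n_starts):
            starts.append(base * np.exp(rng.uniform(-1.0, 1.0, size=base.size)))
        return starts

    def fit(self, n_starts: int = 8, seed: int = 0) -> "RecoveryResults":
        """Least-squares fit with multi-start initialization."""
        func = one_component if self.n_components == 1 else two_component
        lo = np.tile([A_BOUNDS[0], B_BOUNDS[0]], self.n_components)
        hi = np.tile([A_BOUNDS[1], B_BOUNDS[1]], self.n_components)

        def residuals(p):
            return func(self.times, *p) - self.values

        rng = np.random.default_rng(seed)
        best = None
        best_sse = np.inf
        for start in self._starts(n_starts, rng):
            p0 = np.clip(start, lo, hi)
            try:
                sol = optimize.least_squares(
                    residuals, p0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-12
                )
            except Exception:
                continue
            sse = 2.0 * sol.cost
            if sol.success and sse < best_sse - 1e-15:
                best, best_sse = sol, sse
        if best is None:
            raise FitError("no start converged", best_sse)

        params = best.x
        flags = []
        if self.n_components == 2 and params[3] > params[1]:
            params = np.array([params[2], params[3], params[0], params[1]])
        if self.n_components == 2 and abs(params[1] - params[3]) <= 0.01 * params[1]:
            flags.append("components indistinguishable")
        for j in (1, 3)[: self.n_components]:
            if np.isclose(params[j], B_BOUNDS[0]) or np.isclose(params[j], B_BOUNDS[1]):
                flags.append("rate at bound")

        resid = residuals(params)
        sse = float(resid @ resid)
        J = best.jac
        dof = max(len(self.times) - len(params), 1)
        s2 = sse / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(len(params), np.nan)
        return RecoveryResults(
            model=self, params=params, bse=bse, ssr=sse, flags=tuple(flags)
        )


def _two_component_halftime(a, b, c, d):
    """Smallest t with y(t) = (a + c) / 2, bisected to 1e-6 s."""
    target = 0.5 * (a + c)

    def f(t):
        return two_component(t, a, b, c, d) - target

    hi = np.log(2.0) / min(b, d)
    while f(hi) < 0:
        hi *= 2.0
    lo = 0.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class RecoveryResults:
    """Fit results: estimates, uncertainties and diagnostics."""

    model: ExponentialRecoveryModel
    params: np.ndarray
    bse: np.ndarray
    ssr: float
    flags: tuple = ()

    @property
    def n_components(self) -> int:
        return self.model.n_components

    @property
    def param_names(self):
        return ("a", "b") if self.n_components == 1 else ("a", "b", "c", "d")

    @property
    def nobs(self) -> int:
        return len(self.model.times)

    @property
    def df_resid(self) -> int:
        return self.nobs - len(self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.times)

    @property
    def resid(self) -> np.ndarray:
        return self.model.values - self.fittedvalues

    def predict(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self.n_components == 1:
            return one_component(times, *self.params)
        return two_component(times, *self.params)

    @property
    def rsquared(self) -> float:
        y = self.model.values
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            return 1.0 if self.ssr < 1e-30 else 0.0
        return 1.0 - self.ssr / ss_tot

    @property
    def t_half(self) -> float:
        """Half-recovery time in seconds."""
        if self.n_components == 1:
            return float(np.log(2.0) / self.params[1])
        a, b, c, d = self.params
        return float(_two_component_halftime(a, b, c, d))

    @property
    def aic(self) -> float:
        n = self.nobs
        k = len(self.params)
        return n * np.log(max(self.ssr, 1e-300) / n) + 2 * k

    def compare_f_test(self, restricted: "RecoveryResults"):
        """Nested F-test against a restricted (one-component) fit.

        F = ((SSE_1 - SSE_2) / 2) / (SSE_2 / (n - 4)); returns (F, p, df).
        """
        if restricted.nobs != self.nobs:
            raise ValueError("fits must be on identical data")
        df_num = len(self.params) - len(restricted.params)
        if df_num <= 0:
            raise ValueError("compare_f_test expects the richer model as self")
        df_den = self.nobs - len(self.params)
        num = (restricted.ssr - self.ssr) / df_num
        den = self.ssr / df_den
        if num <= 0 or den <= 0:
            return 0.0, 1.0, (df_num, df_den)
        F = num / den
        p = float(stats.f.sf(F, df_num, df_den))
        return float(F), p, (df_num, df_den)

    def summary(self) -> str:
        lines = [
            f"Exponential recovery fit ({self.n_components} component"
            f"{'s' if self.n_components == 2 else ''})",
            f"  n obs: {self.nobs}    SSE: {self.ssr:.6g}    "
            f"R^2: {self.rsquared:.4f}    AIC: {self.aic:.2f}",
            f"  t_half: {1000 * self.t_half:.1f} ms",
        ]
        for name, val, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name} = {val:.6g} +/- {se:.3g}")
        for flag in self.flags:
            lines.append(f"  [flag] {flag}")
        return "\n".join(lines)


def fit_one_component(times, values, **kw) -> RecoveryResults:
    return ExponentialRecoveryModel(times, values, 1).fit(**kw)


def fit_two_component(times, values, **kw) -> RecoveryResults:
    return ExponentialRecoveryModel(times, values, 2).fit(**kw)


@dataclass
class ModelSelection:
    choice: str
    f_statistic: float
    p_value: float
    one: RecoveryResults
    two: RecoveryResults
    warning: str | None = None


def select_model(fit1: RecoveryResults, fit2: RecoveryResults, alpha: float = 0.05):
    """Choose between nested one- and two-component fits by F-test.

    The two-component model is kept only when the added component
    significantly improves the fit (p < alpha).
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise ValueError("select_model expects (one-component, two-component) fits")
    warning = None
    if fit2.ssr > fit1.ssr + 1e-8:
        warning = "two-component SSE exceeds one-component SSE (numerical pathology)"
        warnings.warn(warning)
        return ModelSelection("one_component", 0.0, 1.0, fit1, fit2, warning)
    F, p, _ = fit2.compare_f_test(fit1)
    choice = "two_component" if p < alpha else "one_component"
    return ModelSelection(choice, F, p, fit1, fit2, warning)


def halftime_from_curve(fit: RecoveryResults) -> float:
    """Half-recovery time in milliseconds (the field's reporting unit)."""
    return 1000.0 * fit.t_half
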