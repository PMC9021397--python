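"""Survival analysis: Kaplan-Meier, log-rank test, Cox proportional hazards.

All estimators are implemented here directly (product-limit estimator,
observed-minus-expected log-rank statistic with hypergeometric variance,
Newton-Raphson maximization of the Cox partial likelihood with Breslow or
Efron tie handling); external survival libraries are used only as test
oracles.

Follow-up convention: death (or transplant) is the event; everything else
is administrative censoring.  Ties between a death and a censoring at the
same time keep the censored subject in the risk set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "CoxPH",
    "CoxResults",
    "cox_fit",
    "likelihood_ratio_test",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge on the partial likelihood."""


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if not np.all(np.isin(e, (0, 1, True, False))):
        raise ValueError("events must be binary")
    return t, e.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival estimate with risk-table counts.

    ``event_times`` are the distinct times with at least one death;
    ``survival[k]`` is S(t) just after ``event_times[k]``.  ``censor_marks``
    lists censoring times for plotting ticks.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    censor_marks: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.event_times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right")
        return np.where(idx == 0, 1.0,
                        self.survival[np.clip(idx - 1, 0, None)])

    def number_at_risk(self, t) -> np.ndarray:
        """Number still at risk at each queried time (for risk strips)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        all_t = np.sort(self._all_times)
        return (all_t[None, :] >= t[:, None]).sum(axis=1)

    def cumulative_events(self, t) -> np.ndarray:
        """Total deaths observed up to and including each queried time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        cum = np.concatenate([[0], np.cumsum(self.deaths)])
        return cum[idx]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times,
                             "at_risk": self.at_risk,
                             "deaths": self.deaths,
                             "survival": self.survival})


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_j <= t of (1 - d_j / n_j), where d_j is
    the number of deaths and n_j the number at risk at t_j.  Censored
    subjects leave the risk set after their censoring time.
    """
    t, e = _check_times_events(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    at_risk_all = n - first            # subjects with time >= uniq
    deaths_all = np.add.reduceat(e, first)
    has_death = deaths_all > 0
    event_times = uniq[has_death]
    at_risk = at_risk_all[has_death]
    deaths = deaths_all[has_death]
    surv = np.cumprod(1.0 - deaths / at_risk)
    curve = KMCurve(event_times=event_times, at_risk=at_risk,
                    deaths=deaths, survival=surv,
                    censor_marks=np.sort(t[e == 0]))
    curve._all_times = t
    return curve


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(times, events, group) -> LogrankResult:
    """K-sample log-rank test (chi-square, df = k - 1).

    At each distinct death time the observed deaths per group are compared
    with their expectation under the hypergeometric distribution given the
    group risk-set sizes; the variance-covariance is the standard
    multivariate hypergeometric form.
    """
    t, e = _check_times_events(times, events)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise ValueError("group must match times in length")
    levels, gi = np.unique(g, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    death_times = np.unique(t[e == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for tj in death_times:
        at_risk = t >= tj
        nj = int(at_risk.sum())
        dead_here = at_risk & (t == tj) & (e == 1)
        dj = int(dead_here.sum())
        ng = np.bincount(gi[at_risk], minlength=k).astype(float)
        dg = np.bincount(gi[dead_here], minlength=k).astype(float)
        O += dg
        E += dj * ng / nj
        if nj > 1:
            frac = ng / nj
            hyper = dj * (nj - dj) / (nj - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return LogrankResult(statistic=stat, p_value=p, df=df, observed=O,
                         expected=E)


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_loglik_grad_hess(beta, X, t, e, tie_method):
    """Partial log-likelihood, gradient, Hessian (negative information)."""
    n, p = X.shape
    order = np.argsort(-t, kind="stable")  # descending time
    Xo, to, eo = X[order], t[order], e[order]
    eta = Xo @ beta
    # numeric guard: center the linear predictor
    eta -= eta.max() if eta.size else 0.0
    r = np.exp(eta)
    rx = Xo * r[:, None]
    rxx = np.einsum("ni,nj->nij", Xo, rx)
    # cumulative risk-set sums going down the sorted (descending) array
    S0 = np.cumsum(r)
    S1 = np.cumsum(rx, axis=0)
    S2 = np.cumsum(rxx, axis=0)
    # index of the last subject sharing each time (risk set = t >= t_i)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and to[j + 1] == to[i]:
            j += 1
        # subjects i..j share this time; risk set is everyone up to j
        dead = np.flatnonzero(eo[i:j + 1] == 1) + i
        d = dead.size
        if d > 0:
            s0, s1, s2 = S0[j], S1[j], S2[j]
            sum_eta = eta[dead].sum()
            sum_x = Xo[dead].sum(axis=0)
            if tie_method == "breslow" or d == 1:
                ll += sum_eta - d * np.log(s0)
                grad += sum_x - d * s1 / s0
                hess -= d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
            elif tie_method == "efron":
                rd = r[dead].sum()
                s1d = rx[dead].sum(axis=0)
                s2d = rxx[dead].sum(axis=0)
                ll += sum_eta
                grad += sum_x
                for m in range(d):
                    f = m / d
                    phi0 = s0 - f * rd
                    phi1 = s1 - f * s1d
                    phi2 = s2 - f * s2d
                    ll -= np.log(phi0)
                    grad -= phi1 / phi0
                    hess -= phi2 / phi0 - np.outer(phi1 / phi0, phi1 / phi0)
            else:
                raise ValueError(f"unknown tie_method {tie_method!r}")
        i = j + 1
    return ll, grad, hess


@dataclass
class CoxResults:
    """Fitted Cox model: log-hazard ratios, Wald CIs and likelihood-ratio test.

    ``hr`` is exp(coefficient); 95% confidence intervals are Wald intervals
    on the log-hazard scale from the inverse observed information.
    """

    coefficients: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    tie_method: str
    n: int
    n_events: int
    n_iter: int
    separation_flag: bool = False

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coefficients)

    @property
    def ci95(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.coefficients - z * self.se)
        hi = np.exp(self.coefficients + z * self.se)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    @property
    def zscores(self) -> pd.Series:
        return self.coefficients / self.se

    @property
    def wald_p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zscores)),
                         index=self.coefficients.index)

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def lrt_p(self) -> float:
        return float(stats.chi2.sf(self.lrt_statistic,
                                   len(self.coefficients)))

    def summary(self) -> str:
        ci = self.ci95
        lines = [
            f"Cox proportional hazards ({self.tie_method} ties)",
            f"  n = {self.n}, events = {self.n_events}, "
            f"iterations = {self.n_iter}",
            f"  partial log-likelihood = {self.loglik:.4f} "
            f"(null {self.loglik_null:.4f})",
            f"  LRT chi2({len(self.coefficients)}) = "
            f"{self.lrt_statistic:.4f}, p = {self.lrt_p:.3g}",
            "",
            f"  {'covariate':<28}{'coef':>9}{'HR':>9}{'95% CI':>19}"
            f"{'p':>10}",
        ]
        for name in self.coefficients.index:
            lines.append(
                f"  {name:<28}{self.coefficients[name]:>9.4f}"
                f"{self.hr[name]:>9.3f}"
                f"  ({ci.loc[name, 'hr_lower']:.3f}-"
                f"{ci.loc[name, 'hr_upper']:.3f})".ljust(66)
                + f"{self.wald_p[name]:>10.3g}")
        if self.separation_flag:
            lines.append("  warning: possible monotone likelihood "
                         "(perfect separation)")
        return "\n".join(lines)


class CoxPH:
    """Cox proportional-hazards model fit by Newton-Raphson.

    Parameters
    ----------
    X : DataFrame or 2-D array
        Covariate matrix (categorical covariates already expanded to
        indicators against their reference level).
    times, events : arrays
        Follow-up time and event indicator (1 = death).
    tie_method : {"breslow", "efron"}
    """

    def __init__(self, X, times, events, tie_method: str = "breslow"):
        if isinstance(X, pd.DataFrame):
            self.names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.atleast_2d(np.asarray(X, dtype=float))
            if Xv.shape[0] == 1 and np.asarray(times).size > 1:
                Xv = Xv.T
            self.names = [f"x{j}" for j in range(Xv.shape[1])]
        t, e = _check_times_events(times, events)
        if Xv.shape[0] != t.size:
            raise ValueError("X row count must match times")
        if e.sum() < 1:
            raise ValueError("at least one event is required")
        const = np.ptp(Xv, axis=0) == 0
        if np.any(const):
            bad = [n for n, c in zip(self.names, const) if c]
            raise ValueError(f"covariates constant across all subjects: {bad}")
        self.X, self.t, self.e = Xv, t, e
        if tie_method not in ("breslow", "efron"):
            raise ValueError(f"unknown tie_method {tie_method!r}")
        self.tie_method = tie_method

    def fit(self, max_iter: int = 50, tol: float = 1e-9) -> CoxResults:
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll_null, _, _ = _cox_loglik_grad_hess(beta, self.X, self.t, self.e,
                                              self.tie_method)
        ll_prev = ll_null
        hess = None
        for it in range(1, max_iter + 1):
            ll, grad, hess = _cox_loglik_grad_hess(beta, self.X, self.t,
                                                   self.e, self.tie_method)
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step-halving keeps the likelihood ascending
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, _, _ = _cox_loglik_grad_hess(cand, self.X, self.t,
                                                     self.e, self.tie_method)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2
            beta = beta + scale * step
            if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + tol):
                # one full polishing step: quadratic convergence leaves the
                # coefficients accurate well beyond the stopping rule
                _, grad, hess = _cox_loglik_grad_hess(beta, self.X, self.t,
                                                      self.e, self.tie_method)
                try:
                    beta = beta + np.linalg.solve(-hess, grad)
                except np.linalg.LinAlgError:
                    pass
                ll_prev = ll_new
                break
            ll_prev = ll_new
        else:
            _, grad, _ = _cox_loglik_grad_hess(beta, self.X, self.t, self.e,
                                               self.tie_method)
            raise ConvergenceError(
                f"no convergence after {max_iter} iterations; "
                f"last gradient norm {np.linalg.norm(grad):.3g}")
        ll, grad, hess = _cox_loglik_grad_hess(beta, self.X, self.t, self.e,
                                               self.tie_method)
        separation = bool(np.any(np.abs(beta) > 15))
        cov = np.linalg.pinv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return CoxResults(coefficients=pd.Series(beta, index=self.names),
                          se=pd.Series(se, index=self.names),
                          loglik=float(ll), loglik_null=float(ll_null),
                          tie_method=self.tie_method, n=self.t.size,
                          n_events=int(self.e.sum()), n_iter=it,
                          separation_flag=separation)


def cox_fit(X, times, events, tie_method: str = "breslow") -> CoxResults:
    """Functional front door to :class:`CoxPH`."""
    return CoxPH(X, times, events, tie_method=tie_method).fit()


def likelihood_ratio_test(full: CoxResults, null_loglik: float | None = None
                          ) -> tuple[float, float]:
    """LRT of a fitted Cox model against a nested null.

    Returns (statistic, p) with statistic = 2*(loglik - loglik_null) and p
    from a chi-square with df = number of coefficients.
    """
    ll0 = full.loglik_null if null_loglik is None else null_loglik
    stat = 2.0 * (full.loglik - ll0)
    if stat < -1e-8:
        raise ValueError(
            f"negative LRT statistic {stat:.3g}: models are not nested or "
            "the fit did not converge")
    stat = max(stat, 0.0)
    df = len(full.coefficients)
    p = float(stats.chi2.sf(stat, df)) if df else 1.0
    return stat, p
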