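"""Survival machinery: Kaplan-Meier, log-rank, Cox PH, Schoenfeld diagnostics.

All estimators are implemented here from first principles (they are part
of the package's contract, not delegated):

* product-limit survival estimates with Greenwood variance and 95%
  confidence intervals on the log scale,
* the k-sample log-rank test over pooled event times,
* Cox proportional-hazards regression by Newton-Raphson maximization of
  the partial likelihood with the Efron correction for tied event
  times, Wald tests and confidence intervals,
* the enter-method model-building convention: every covariate
  significant in a univariable fit (p <= 0.05 for any of its levels)
  enters one joint multivariable model,
* scaled Schoenfeld residuals with a correlation-with-time test of the
  proportional-hazards assumption.

Overall survival (OS) counts death from any cause as the event;
disease-specific survival (DSS) counts only disease-attributed deaths
and censors other deaths at the same time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "derive_endpoints",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "enter_method_pipeline",
    "schoenfeld_check",
    "plot_km",
    "plot_schoenfeld",
]

_Z95 = 1.959963984540054


def derive_endpoints(records):
    """OS and DSS (time, event) pairs from survival columns.

    OS events are deaths from any cause.  For DSS a death not attributed
    to the disease is treated as censoring at the same time.  Returns
    ``((os_time, os_event), (dss_time, dss_event))``.
    """
    t = np.asarray(records["os_time"], dtype=float)
    if np.any(t < 0):
        raise ValueError("negative survival time")
    os_e = np.asarray(records["os_event"], dtype=bool)
    dss_e = np.asarray(records["dss_event"], dtype=bool)
    if np.any(dss_e & ~os_e):
        raise ValueError("disease-specific events must be a subset of deaths")
    return (t, os_e), (t.copy(), dss_e)


@dataclass
class KMCurve:
    """Product-limit estimate over the distinct event times."""

    times: np.ndarray        # distinct event times, increasing
    survival: np.ndarray     # S(t) just after each event time
    variance: np.ndarray     # Greenwood variance of S(t)
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray      # n at risk just before each event time
    n_events: np.ndarray


def km_estimate(times, events):
    """Kaplan-Meier estimator with Greenwood 95% CIs on the log scale."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    if times.max() == 0:
        raise ValueError("all survival times are zero")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e])
    n = t.size
    surv, var_terms = [], []
    s = 1.0
    cum = 0.0
    at_risk, n_ev = [], []
    for et in event_times:
        r = np.count_nonzero(t >= et)
        d = np.count_nonzero((t == et) & e)
        at_risk.append(r)
        n_ev.append(d)
        s *= (r - d) / r
        if r > d:
            cum += d / (r * (r - d))
        else:
            cum = np.inf
        surv.append(s)
        var_terms.append(cum)
    surv = np.asarray(surv)
    cumvar = np.asarray(var_terms)
    with np.errstate(invalid="ignore"):
        greenwood = np.where(surv > 0, surv**2 * cumvar, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_se = np.sqrt(cumvar)
        lo = np.where(surv > 0, surv * np.exp(-_Z95 * log_se), 0.0)
        hi = np.where(surv > 0, surv * np.exp(_Z95 * log_se), 0.0)
    return KMCurve(
        times=event_times,
        survival=surv,
        variance=greenwood,
        ci_low=np.clip(lo, 0.0, 1.0),
        ci_high=np.clip(hi, 0.0, 1.0),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
    )


def survival_at(curve: KMCurve, t):
    """Survival estimate and 95% CI at time ``t`` (step-function lookup)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0, 1.0, 1.0
    return (
        float(curve.survival[idx]),
        float(curve.ci_low[idx]),
        float(curve.ci_high[idx]),
    )


def logrank_test(group_times, group_events):
    """k-sample log-rank test.

    ``group_times`` / ``group_events`` are sequences of per-group
    arrays.  Returns ``(chi2, df, p)``; with no events overall the test
    is undefined and ``(nan, df, nan)`` is returned.
    """
    k = len(group_times)
    if k < 2:
        raise ValueError("need at least two groups")
    times = [np.asarray(t, float) for t in group_times]
    events = [np.asarray(e, bool) for e in group_events]
    for t in times:
        if t.size == 0:
            raise ValueError("empty group")
    all_t = np.concatenate(times)
    all_e = np.concatenate(events)
    group = np.concatenate([np.full(t.size, g) for g, t in enumerate(times)])
    if not all_e.any():
        return float("nan"), k - 1, float("nan")
    event_times = np.unique(all_t[all_e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for et in event_times:
        at_risk = all_t >= et
        n_j = np.array([np.count_nonzero(at_risk & (group == g)) for g in range(k)])
        n_tot = n_j.sum()
        dying = (all_t == et) & all_e
        d_j = np.array([np.count_nonzero(dying & (group == g)) for g in range(k)])
        d_tot = d_j.sum()
        observed += d_j
        expected += d_tot * n_j / n_tot
        if n_tot > 1:
            frac = n_j / n_tot
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            var += factor * (np.diag(frac) - np.outer(frac, frac))
    z = (observed - expected)[: k - 1]
    v = var[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    p = float(stats.chi2.sf(chi2, k - 1))
    return chi2, k - 1, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    names: list = field(default_factory=list)
    cov: np.ndarray | None = None
    n: int = 0
    n_events: int = 0
    tie_handling: str = "efron"

    def summary(self):
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hr,
                "HR 95% low": self.ci_low,
                "HR 95% high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _efron_quantities(x, xb, t_sorted, e_sorted):
    """Log partial likelihood, gradient and Hessian under Efron ties.

    Inputs are sorted by ascending time.  Vectorized over event times:
    suffix sums give the risk-set aggregates S0 (scalar), S1 (p-vector)
    and S2 (p x p) at each tied-group start; the Efron inner terms are
    expanded to one row per (event, within-tie index).
    """
    n, p = x.shape
    w = np.exp(xb)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]

    uniq, starts = np.unique(t_sorted, return_index=True)
    g_of = np.repeat(np.arange(starts.size), np.diff(np.append(starts, n)))

    def suffix(groupwise):
        return np.cumsum(groupwise[::-1], axis=0)[::-1]

    s0_g = suffix(np.add.reduceat(w, starts))
    s1_g = suffix(np.add.reduceat(wx, starts))
    s2_g = suffix(np.add.reduceat(wxx, starts))

    ev = np.flatnonzero(e_sorted)
    if ev.size == 0:
        raise ValueError("no events")
    g_ev = g_of[ev]
    # within-group event order l = 0..d-1 and tie sums
    d_g = np.bincount(g_ev, minlength=starts.size)
    t0_g = np.bincount(g_ev, weights=w[ev], minlength=starts.size)
    t1_g = np.zeros_like(s1_g)
    t2_g = np.zeros_like(s2_g)
    np.add.at(t1_g, g_ev, wx[ev])
    np.add.at(t2_g, g_ev, wxx[ev])

    order_within = np.zeros(ev.size, dtype=float)
    seen = {}
    for i, g in enumerate(g_ev):
        order_within[i] = seen.get(g, 0)
        seen[g] = seen.get(g, 0) + 1
    frac = order_within / d_g[g_ev]

    denom = s0_g[g_ev] - frac * t0_g[g_ev]
    num1 = s1_g[g_ev] - frac[:, None] * t1_g[g_ev]
    num2 = s2_g[g_ev] - frac[:, None, None] * t2_g[g_ev]

    zbar = num1 / denom[:, None]
    loglik = float(xb[ev].sum() - np.log(denom).sum())
    grad = x[ev].sum(axis=0) - zbar.sum(axis=0)
    hess = -(
        (num2 / denom[:, None, None]).sum(axis=0)
        - np.einsum("ij,ik->jk", zbar, zbar)
    )
    return loglik, grad, hess, ev, zbar, denom


def cox_fit(X, times, events, names=None, max_iter=100, tol=1e-9):
    """Fit a Cox PH model by Newton-Raphson on the Efron partial likelihood.

    ``X`` is an (n, p) design matrix (categorical covariates must already
    be reference-coded).  Raises on constant covariates; warns when the
    fit drifts toward monotone-likelihood separation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if events.sum() < p:
        raise ValueError("fewer events than covariates")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate in design matrix")

    order = np.argsort(times, kind="stable")
    xs, ts, es = X[order], times[order], events[order]
    # center covariates for numerical stability; coefficients unaffected
    center = xs.mean(axis=0)
    xs = xs - center

    beta = np.zeros(p)
    loglik, grad, hess, *_ = _efron_quantities(xs, xs @ beta, ts, es)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving keeps the partial likelihood increasing
        for _ in range(30):
            new_beta = beta + step
            try:
                new = _efron_quantities(xs, xs @ new_beta, ts, es)
            except FloatingPointError:
                new = None
            if new is not None and np.isfinite(new[0]) and new[0] >= loglik - 1e-12:
                break
            step = step / 2.0
        beta = new_beta
        new_loglik, grad, hess = new[0], new[1], new[2]
        if abs(new_loglik - loglik) < tol and np.max(np.abs(grad)) < 1e-6:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if np.max(np.abs(beta)) > 15:
        warnings.warn("possible separation: |coef| very large", RuntimeWarning)

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    fit = CoxFit(
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=np.exp(beta - _Z95 * se),
        ci_high=np.exp(beta + _Z95 * se),
        p=pvals,
        loglik=loglik,
        converged=converged,
        names=list(names),
        cov=cov,
        n=n,
        n_events=int(events.sum()),
    )
    if not converged:
        warnings.warn("Cox fit did not converge; no HRs should be reported",
                      RuntimeWarning)
    return fit


def _design_from_categorical(series, reference):
    """Reference-coded dummy design for one categorical covariate."""
    levels = [reference] + [l for l in pd.unique(series) if l != reference]
    cols = {}
    for lev in levels[1:]:
        cols[str(lev)] = (series == lev).astype(float).to_numpy()
    return cols, levels


def enter_method_pipeline(data, covariates, time_col="os_time",
                          event_col="os_event", alpha=0.05, references=None):
    """Univariable screening followed by one joint multivariable fit.

    Each covariate in ``covariates`` (columns of ``data``; categorical
    columns are reference-coded, numeric ones entered as-is) is fit
    alone; covariates with any level at Wald p <= alpha enter the
    multivariable model together (the enter method: no stepwise
    refinement).  ``references`` maps covariate name to reference level
    (default: first sorted level; for a subtype factor pass the
    best-prognosis group).

    Returns a dict with ``univariable`` (name -> CoxFit), ``selected``
    (list of covariate names) and ``multivariable`` (CoxFit or None).
    """
    references = references or {}
    times = data[time_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=bool)

    def design_for(var):
        col = data[var]
        if col.dtype.kind in "ifb" and col.nunique() > 4:
            return {var: col.to_numpy(dtype=float)}
        ref = references.get(var, sorted(col.unique())[0])
        cols, _ = _design_from_categorical(col, ref)
        return {f"{var}[{lev}]": arr for lev, arr in cols.items()}

    uni = {}
    selected = []
    for var in covariates:
        cols = design_for(var)
        X = np.column_stack(list(cols.values()))
        fit = cox_fit(X, times, events, names=list(cols.keys()))
        uni[var] = fit
        if fit.converged and np.any(fit.p <= alpha):
            selected.append(var)

    multi = None
    if selected:
        all_cols = {}
        for var in selected:
            all_cols.update(design_for(var))
        X = np.column_stack(list(all_cols.values()))
        multi = cox_fit(X, times, events, names=list(all_cols.keys()))
    return {"univariable": uni, "selected": selected, "multivariable": multi}


def plot_km(curves, path=None, title="Overall survival"):
    """Step plot of one or more KM curves with shaded 95% CIs.

    ``curves`` maps group label to :class:`KMCurve`.  Saves to ``path``
    when given, else returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        (line,) = ax.step(t, s, where="post", label=label)
        lo = np.concatenate([[1.0], curve.ci_low])
        hi = np.concatenate([[1.0], curve.ci_high])
        ax.fill_between(t, lo, hi, step="post", alpha=0.15,
                        color=line.get_color())
    ax.set_xlabel("years since surgery")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig


def plot_schoenfeld(check_result, path=None):
    """Scatter of scaled Schoenfeld residuals against event time."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    resid = check_result.attrs["residuals"]
    t = check_result.attrs["event_times"]
    p = resid.shape[1]
    fig, axes = plt.subplots(1, p, figsize=(4.5 * p, 3.5), squeeze=False)
    for j in range(p):
        ax = axes[0, j]
        ax.scatter(t, resid[:, j], s=8, alpha=0.6)
        ax.axhline(0.0, color="gray", lw=0.8)
        row = check_result.iloc[j]
        ax.set_title(f"{row['covariate']} (r={row['correlation']:.2f}, "
                     f"p={row['p']:.3f})")
        ax.set_xlabel("event time")
        ax.set_ylabel("scaled residual")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig


def schoenfeld_check(fit: CoxFit, X, times, events, transform="km"):
    """Scaled Schoenfeld residuals and a correlation-with-time PH test.

    Residuals exist only at event times.  The scaled residual for event
    i is ``beta + m * cov(beta) @ (x_i - xbar(t_i))`` (Grambsch-Therneau
    scaling with the number of events m).  Each covariate's residuals
    are correlated (Pearson) against transformed time: ``"km"`` uses
    ``1 - S_KM(t)`` (left-continuous), ``"identity"`` raw time.

    Returns a data frame with one row per covariate (correlation, p)
    and the residual matrix in ``.attrs["residuals"]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(times).size:
        X = X.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 2:
        raise ValueError("need at least two events")
    order = np.argsort(times, kind="stable")
    xs, ts, es = X[order] - X.mean(axis=0), times[order], events[order]
    _, _, _, ev, zbar, _ = _efron_quantities(xs, xs @ fit.coef, ts, es)
    resid = xs[ev] - zbar
    m = ev.size
    scaled = fit.coef + m * (resid @ fit.cov.T)
    t_ev = ts[ev]
    if transform == "km":
        curve = km_estimate(times, events)
        # left-continuous KM: S just before each event time
        idx = np.searchsorted(curve.times, t_ev, side="left") - 1
        s_before = np.where(idx >= 0, curve.survival[np.maximum(idx, 0)], 1.0)
        g = 1.0 - s_before
    elif transform == "identity":
        g = t_ev
    else:
        raise ValueError(f"unknown transform {transform!r}")
    rows = []
    for j, name in enumerate(fit.names):
        r, p = stats.pearsonr(g, scaled[:, j])
        rows.append({"covariate": name, "correlation": float(r), "p": float(p)})
    out = pd.DataFrame(rows)
    out.attrs["residuals"] = scaled
    out.attrs["event_times"] = t_ev
    return out
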