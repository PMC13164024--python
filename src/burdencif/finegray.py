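"""Fine-Gray subdistribution-hazard regression.

Regression on the subdistribution hazard of one event type in the presence
of a competing event (Fine & Gray 1999).  Subjects who fail from the
competing cause remain in the risk set after their failure time with an
inverse-probability-of-censoring weight

    w_i(t) = G(t-) / G(min(T_i, t)-)

where ``G`` is the Kaplan-Meier estimate of the censoring distribution
(both event types treated as censorings of the censoring process).  The
weighted partial likelihood is maximized by Newton-Raphson with
step-halving; ties among failure times use the Breslow approximation.
The reported variance is a cluster-robust sandwich: score residuals are
summed within clusters before the outer product, so families contribute
one aggregated residual each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FineGrayFit", "fit_fine_gray"]

_MAX_ITER = 50
_TOL = 1e-9
_MAX_HALVINGS = 10
_COND_LIMIT = 1e12


@dataclass
class FineGrayFit:
    """Result of a Fine-Gray fit.

    Coefficients are log subdistribution hazard ratios; ``hr`` is their
    exponential.  ``se_robust`` is the cluster-robust (sandwich) standard
    error used for the Wald tests and 95% confidence intervals;
    ``se_model`` is the model-based (inverse-information) one.
    ``estimable`` flags covariates with enough variation among subjects
    experiencing the cause of interest to identify a coefficient;
    non-estimable covariates carry NaN coefficients.
    """

    terms: list[str]
    coef: np.ndarray
    se_model: np.ndarray
    se_robust: np.ndarray
    loglik: float
    n_params: int
    n_events: int
    n_obs: int
    converged: bool
    estimable: np.ndarray
    cause: int = 1
    n_iter: int = 0

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.coef - 1.96 * self.se_robust)
        hi = np.exp(self.coef + 1.96 * self.se_robust)
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z2 = (self.coef / self.se_robust) ** 2
        return stats.chi2.sf(z2, df=1)

    @property
    def aic(self) -> float:
        if not self.converged or not np.isfinite(self.loglik):
            return np.inf
        return -2.0 * self.loglik + 2.0 * self.n_params

    def summary(self):
        import pandas as pd

        ci = self.ci95
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "se_robust": self.se_robust,
                "p": self.wald_p,
                "estimable": self.estimable,
            }
        )


def censoring_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G.

    Censorings (event == 0) are the "events" of this process; failures of
    either cause are treated as censorings of it.  At tied times failures
    are taken to precede censorings, so the at-risk count for a censoring
    at t excludes subjects failing exactly at t is NOT applied: the
    at-risk set is {T >= t}, the standard product-limit form.

    Returns (jump_times, g_values) with g right-continuous.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    cens_sorted = (event[order] == 0).astype(float)
    uniq, idx = np.unique(t_sorted, return_index=True)
    n = len(time)
    at_risk = n - idx
    d_cens = np.add.reduceat(cens_sorted, idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d_cens / at_risk
    g = np.cumprod(factors)
    return uniq, g


def _g_left(jump_times: np.ndarray, g: np.ndarray, t: np.ndarray) -> np.ndarray:
    """G(t-): left-continuous evaluation of the censoring KM."""
    idx = np.searchsorted(jump_times, t, side="left") - 1
    out = np.where(idx >= 0, g[np.clip(idx, 0, None)], 1.0)
    return out


def _fg_weight_matrix(time, event, cause):
    """Risk-set weight matrix W[d, j] for each cause-of-interest event time.

    Rows index the unique times with >= 1 event of the target cause,
    columns index subjects.  W is 1 for subjects still at risk (T_j >= t),
    G(t-)/G(T_j-) for subjects who failed earlier from the competing
    cause, and 0 otherwise.
    """
    is_target = event == cause
    ev_times = np.unique(time[is_target])
    gj, gv = censoring_survival(time, event)
    g_at_t = _g_left(gj, gv, ev_times)          # G(t-), per event time
    g_at_T = _g_left(gj, gv, time)              # G(T_j-), per subject

    tt = ev_times[:, None]
    still_at_risk = time[None, :] >= tt
    competing_past = (event != cause) & (event != 0)
    comp = competing_past[None, :] & (time[None, :] < tt)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = g_at_t[:, None] / g_at_T[None, :]
    W = np.where(still_at_risk, 1.0, 0.0)
    W = np.where(comp, ratio, W)
    # multiplicity of target-cause events at each row time (Breslow ties)
    d_mult = np.array([np.sum(time[is_target] == t) for t in ev_times], dtype=float)
    return ev_times, W, d_mult


def _loglik_score_hess(beta, X, W, ev_times, d_mult, time, event, cause):
    """Breslow-tie weighted partial likelihood, score and information."""
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; cancels in all ratios
    r = np.exp(eta)
    wr = W * r[None, :]                      # D x n
    S0 = wr.sum(axis=1)                      # D
    S1 = wr @ X                              # D x p
    xbar = S1 / S0[:, None]

    is_target = event == cause
    # numerator: sum over event subjects of eta_i (Breslow)
    ll = float(eta[is_target].sum() - (d_mult * np.log(S0)).sum())
    # score: sum_i x_i - sum_d d_mult * xbar_d
    score = X[is_target].sum(axis=0) - d_mult @ xbar
    # information: sum_d d_mult * (S2/S0 - xbar xbar')
    p = X.shape[1]
    info = np.zeros((p, p))
    for d in range(len(S0)):
        xc = X - xbar[d]
        info += d_mult[d] * (xc.T * wr[d]) @ xc / S0[d]
    return ll, score, info, wr, S0, xbar


def _score_residuals(X, W, d_mult, S0, xbar, wr, time, event, cause, ev_times):
    """Per-subject score residuals of the weighted partial likelihood."""
    n, p = X.shape
    is_target = event == cause
    res = np.zeros((n, p))
    # event part: subject's own event contribution x_i - xbar(t_i)
    d_idx = np.searchsorted(ev_times, time[is_target])
    res[is_target] = X[is_target] - xbar[d_idx]
    # expectation part: - sum_d d_mult[d] * w_dj r_j (x_j - xbar_d) / S0_d
    A = (d_mult / S0)[:, None] * wr          # D x n, includes r_j via wr
    colsum = A.sum(axis=0)                   # per subject j
    res -= colsum[:, None] * X - A.T @ xbar
    return res


def fit_fine_gray(
    data,
    covariates,
    cause: int = 1,
    cluster=None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> FineGrayFit:
    """Fit a Fine-Gray model for the given cause.

    Parameters
    ----------
    data
        A :class:`~burdencif.io_cohort.CompetingRisksDataset` or any object
        with ``time`` and ``event`` arrays (event coded 0=censored, 1, 2)
        and optionally ``cluster``.
    covariates
        DataFrame or 2-D array of numeric covariates (rows follow data).
    cause
        Event code of the cause of interest (its competitor is the other
        nonzero code).
    cluster
        Cluster labels for the robust variance; defaults to ``data.cluster``
        or, absent that, one cluster per subject.
    """
    import pandas as pd

    time = np.asarray(data.time, dtype=float)
    event = np.asarray(data.event, dtype=int)
    if isinstance(covariates, pd.DataFrame):
        terms = list(covariates.columns)
        X_all = covariates.to_numpy(dtype=float)
    else:
        X_all = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X_all.shape[0] != len(time):
            X_all = X_all.T
        terms = [f"x{i}" for i in range(X_all.shape[1])]
    if cluster is None:
        cluster = getattr(data, "cluster", None)
    if cluster is None:
        cluster = np.arange(len(time))
    cluster = np.asarray(cluster)

    if not np.all(np.isfinite(X_all)):
        raise ValueError("covariates must be finite")
    n_events = int(np.sum(event == cause))
    if n_events == 0:
        raise ValueError(f"no events of cause {cause} in the data")

    # estimability: a coefficient is identified only if the covariate varies
    # among subjects experiencing the target cause (the score otherwise has
    # zero weighted variance); refined below by a Hessian condition check.
    estimable = np.array(
        [
            len(np.unique(X_all[event == cause, j])) >= 2
            and len(np.unique(X_all[:, j])) >= 2
            for j in range(X_all.shape[1])
        ]
    )
    keep = np.flatnonzero(estimable)
    p_all = X_all.shape[1]
    coef = np.full(p_all, np.nan)
    se_m = np.full(p_all, np.nan)
    se_r = np.full(p_all, np.nan)

    if len(keep) == 0:
        return FineGrayFit(
            terms=terms, coef=coef, se_model=se_m, se_robust=se_r,
            loglik=np.nan, n_params=0, n_events=n_events, n_obs=len(time),
            converged=False, estimable=estimable, cause=cause,
        )

    X = X_all[:, keep]
    # center for numerical stability (shifts cancel in the partial likelihood)
    x_center = X.mean(axis=0)
    Xc = X - x_center

    ev_times, W, d_mult = _fg_weight_matrix(time, event, cause)

    beta = np.zeros(len(keep))
    ll, score, info, wr, S0, xbar = _loglik_score_hess(
        beta, Xc, W, ev_times, d_mult, time, event, cause
    )
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        cond = np.linalg.cond(info) if info.size else np.inf
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            break
        step = np.linalg.solve(info, score)
        new_beta = beta + step
        new = _loglik_score_hess(new_beta, Xc, W, ev_times, d_mult, time, event, cause)
        halvings = 0
        while new[0] < ll and halvings < _MAX_HALVINGS:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new = _loglik_score_hess(new_beta, Xc, W, ev_times, d_mult, time, event, cause)
        delta = new[0] - ll
        beta = new_beta
        ll, score, info, wr, S0, xbar = new
        if abs(delta) < tol:
            converged = True
            break

    cond = np.linalg.cond(info) if info.size else np.inf
    ill = not np.isfinite(cond) or cond > _COND_LIMIT
    if ill:
        converged = False
        estimable = estimable.copy()
        estimable[keep] = False

    if not ill:
        info_inv = np.linalg.inv(info)
        resid = _score_residuals(
            Xc, W, d_mult, S0, xbar, wr, time, event, cause, ev_times
        )
        # sum score residuals within clusters before the outer product
        order = np.argsort(cluster, kind="stable")
        _, start = np.unique(cluster[order], return_index=True)
        summed = np.add.reduceat(resid[order], start, axis=0)
        meat = summed.T @ summed
        robust = info_inv @ meat @ info_inv
        coef[keep] = beta
        se_m[keep] = np.sqrt(np.diag(info_inv))
        se_r[keep] = np.sqrt(np.diag(robust))

    return FineGrayFit(
        terms=terms,
        coef=coef,
        se_model=se_m,
        se_robust=se_r,
        loglik=ll if not ill else np.nan,
        n_params=int(len(keep)) if not ill else 0,
        n_events=n_events,
        n_obs=len(time),
        converged=converged,
        estimable=estimable,
        cause=cause,
        n_iter=n_iter,
    )
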