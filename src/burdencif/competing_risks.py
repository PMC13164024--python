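"""Survival and competing-risks estimators.

Kaplan-Meier curves and the k-sample log-rank test for the composite
endpoint (any dementia onset), Aalen-Johansen cumulative incidence
functions for the cause-specific endpoints (AD vs FTD onset), Gray's
k-sample test comparing CIFs, and Fine-Gray subdistribution-hazard
regression (re-exported from :mod:`burdencif.finegray`).

Kaplan-Meier and Aalen-Johansen share one tie convention (all events at a
tied time processed against the same at-risk count, censorings after
events), which makes the conservation identity

    CIF_1(t) + CIF_2(t) + S(t) = 1

hold to machine precision at every time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .finegray import FineGrayFit, fit_fine_gray  # noqa: F401  (re-export)

__all__ = [
    "StepFunction",
    "CIFEstimate",
    "GrayTestResult",
    "kaplan_meier",
    "logrank_test",
    "cif_aalen_johansen",
    "gray_test",
    "fit_fine_gray",
    "FineGrayFit",
]


@dataclass
class StepFunction:
    """Right-continuous step function with value ``init`` before the first jump."""

    x: np.ndarray
    y: np.ndarray
    init: float = 1.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.init)
        return out if out.ndim else float(out)

    def left(self, t):
        """Left-continuous evaluation (value just before t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="left") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.init)
        return out if out.ndim else float(out)


@dataclass
class CIFEstimate:
    """Aalen-Johansen cumulative incidence for one cause (one group)."""

    cause: int
    jump_times: np.ndarray
    cif_values: np.ndarray
    group: object = None

    def __call__(self, t):
        return StepFunction(self.jump_times, self.cif_values, init=0.0)(t)


@dataclass
class GrayTestResult:
    cause: int
    statistic: float
    df: int
    p_value: float


def _risk_table(time, event):
    """Unique times, at-risk counts and per-cause event counts."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    uniq, idx = np.unique(ts, return_index=True)
    at_risk = len(ts) - idx
    counts = {}
    for code in np.unique(es):
        counts[int(code)] = np.add.reduceat((es == code).astype(float), idx)
    zero = np.zeros(len(uniq))
    return uniq, at_risk.astype(float), counts, zero


def kaplan_meier(data=None, time=None, event=None) -> StepFunction:
    """Product-limit estimate of the all-event survival function.

    Accepts a composite-endpoint dataset (event in {0, 1}) or a by-cause
    dataset, in which case any nonzero code counts as an event.
    """
    if data is not None:
        time, event = np.asarray(data.time, float), np.asarray(data.event, int)
    else:
        time, event = np.asarray(time, float), np.asarray(event, int)
    uniq, at_risk, counts, zero = _risk_table(time, event)
    d = sum(counts.get(c, zero) for c in counts if c != 0)
    if np.all(d == 0):
        warnings.warn("no events; survival curve is identically 1", stacklevel=2)
        return StepFunction(uniq, np.ones_like(uniq))
    surv = np.cumprod(1.0 - d / at_risk)
    return StepFunction(uniq, surv)


def logrank_test(data, groups):
    """k-sample log-rank test on the composite endpoint.

    Returns ``(statistic, df, p)``.  Backed by lifelines'
    multivariate log-rank implementation.
    """
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    event_obs = (np.asarray(data.event, int) != 0).astype(int)
    res = multivariate_logrank_test(np.asarray(data.time, float), groups, event_obs)
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def cif_aalen_johansen(data, groups=None, causes=(1, 2)):
    """Aalen-Johansen CIF per cause (and per group, if labels are given).

    CIF_k(t) = sum_{t_i <= t} S(t_i-) d_k(t_i) / n(t_i) with S the
    all-cause Kaplan-Meier estimate.  Returns a dict keyed by cause, or by
    (group, cause) when ``groups`` is not None.
    """
    time = np.asarray(data.time, float)
    event = np.asarray(data.event, int)
    if groups is not None:
        groups = np.asarray(groups)
        out = {}
        for g in np.unique(groups):
            m = groups == g
            sub = _Subset(time[m], event[m])
            for c, est in cif_aalen_johansen(sub, causes=causes).items():
                est.group = g
                out[(g, c)] = est
        return out

    uniq, at_risk, counts, zero = _risk_table(time, event)
    d_all = sum(counts.get(c, zero) for c in counts if c != 0)
    surv = np.cumprod(1.0 - d_all / at_risk)
    s_left = np.concatenate([[1.0], surv[:-1]])
    out = {}
    for c in causes:
        d_c = counts.get(int(c), zero)
        cif = np.cumsum(s_left * d_c / at_risk)
        out[int(c)] = CIFEstimate(cause=int(c), jump_times=uniq, cif_values=cif)
    return out


@dataclass
class _Subset:
    time: np.ndarray
    event: np.ndarray


def gray_test(data, groups, cause: int = 1, rho: float = 0.0) -> GrayTestResult:
    """Gray's k-sample test for equality of cause-specific CIFs.

    Compares the subdistribution hazards across groups using the
    modified risk sets R_g(t) = Y_g(t) (1 - F_g(t-)) / S_g(t-), where F_g
    is the group's Aalen-Johansen CIF for the target cause and S_g its
    all-cause Kaplan-Meier curve (Gray 1988, weight (1-F(t-))^rho, default
    rho = 0).  The covariance of the score vector is estimated from
    per-subject influence functions, including the terms arising from
    estimating F_g and S_g inside the risk weights; the statistic is
    referred to a chi-square with k - 1 degrees of freedom.
    """
    time = np.asarray(data.time, float)
    event = np.asarray(data.event, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if not np.any(event == cause):
        raise ValueError(f"no events of cause {cause}")

    # pooled target-cause event times
    ev_times = np.unique(time[event == cause])
    D = len(ev_times)

    # per-group step quantities on the pooled grid
    Y = np.zeros((k, D))
    dN1 = np.zeros((k, D))
    F_left = np.zeros((k, D))   # F_g(t-)
    S_left = np.ones((k, D))    # S_g(t-)
    group_tables = []
    for gi, g in enumerate(labels):
        m = groups == g
        if not np.any(m):
            raise ValueError(f"group {g!r} is empty")
        tg, eg = time[m], event[m]
        uniq, at_risk, counts, zero = _risk_table(tg, eg)
        d_all = sum(counts.get(c, zero) for c in counts if c != 0)
        d_c = counts.get(int(cause), zero)
        surv = np.cumprod(1.0 - d_all / at_risk)
        s_prev = np.concatenate([[1.0], surv[:-1]])
        cif = np.cumsum(s_prev * d_c / at_risk)
        group_tables.append(
            dict(uniq=uniq, at_risk=at_risk, d_all=d_all, d_c=d_c,
                 surv=surv, cif=cif, mask=m)
        )
        # at-risk count at t is #{T >= t}
        Y[gi] = int(m.sum()) - np.searchsorted(np.sort(tg), ev_times, side="left")
        pos = np.searchsorted(uniq, ev_times)
        has = (pos < len(uniq)) & np.isclose(
            np.where(pos < len(uniq), uniq[np.clip(pos, 0, len(uniq) - 1)], np.nan),
            ev_times,
        )
        dn = np.zeros(D)
        dn[has] = d_c[pos[has]]
        dN1[gi] = dn
        F_left[gi] = StepFunction(uniq, cif, init=0.0).left(ev_times)
        S_left[gi] = StepFunction(uniq, surv, init=1.0).left(ev_times)

    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(Y > 0, Y * (1.0 - F_left) / S_left, 0.0)
    Rtot = R.sum(axis=0)
    ok = Rtot > 0
    dN1tot = dN1.sum(axis=0)
    a = np.where(ok, R / Rtot[None, :], 0.0)

    # pooled CIF left limits for the rho-weight
    if rho != 0.0:
        pooled = cif_aalen_johansen(_Subset(time, event), causes=(cause,))[cause]
        Wt = (1.0 - StepFunction(pooled.jump_times, pooled.cif_values, init=0.0)
              .left(ev_times)) ** rho
    else:
        Wt = np.ones(D)

    z_full = (Wt[None, :] * (dN1 - a * dN1tot[None, :])).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        dGamma = np.where(ok, dN1tot / Rtot, 0.0)

    # influence functions: for subject i in group l,
    #   h_j(i) = int g1_jl(u) dM_1i(u) - int g2_jl(u) dM_i.(u)
    # with (b_jl = 1{j=l} - a_j, c_jl(u) = sum_{t>u} W b_jl Y_l dGamma / S_l(t-))
    #   g1_jl(u) = W(u) b_jl(u) + S_l(u-) c_jl(u) / Y_l(u)
    #   g2_jl(u) = (1 - F_l(u-)) c_jl(u) / Y_l(u)
    H = np.zeros((len(time), k - 1))
    for li, g in enumerate(labels):
        gt = group_tables[li]
        m = gt["mask"]
        tg, eg = time[m], event[m]
        uniq, at_risk, d_all, d_c = gt["uniq"], gt["at_risk"], gt["d_all"], gt["d_c"]
        surv, cif = gt["surv"], gt["cif"]
        s_prev = np.concatenate([[1.0], surv[:-1]])
        f_prev = np.concatenate([[0.0], cif[:-1]])
        Y_l = StepFunction(uniq, at_risk, init=float(m.sum()))  # not used for eval
        for ji in range(k - 1):
            b = (1.0 if ji == li else 0.0) - a[ji]
            # c_jl at pooled event grid: tail-sum of W*b*Y_l*dGamma/S_l(t-),
            # excluding the current time (strictly later times)
            with np.errstate(divide="ignore", invalid="ignore"):
                incr = np.where(S_left[li] > 0, Wt * b * Y[li] * dGamma / S_left[li], 0.0)
            tail = np.concatenate([np.cumsum(incr[::-1])[::-1][1:], [0.0]])
            # c_jl as a right-continuous step function of u on ev_times grid:
            # value after ev_times[d] is tail[d]; before the first event time
            # it is tail[-1+...] = full sum
            full = incr.sum()
            c_fun = StepFunction(ev_times, tail, init=full)

            # g1 on the pooled cause-event grid; the cause-1 martingale is
            # compensated with the pooled null subdistribution hazard:
            # lambda_1l(u) du = (1 - F_l(u-)) / S_l(u-) dGamma(u)
            with np.errstate(divide="ignore", invalid="ignore"):
                g1_pool = Wt * b + np.where(
                    Y[li] > 0, S_left[li] * tail / Y[li], 0.0
                )
                haz1 = np.where(
                    S_left[li] > 0, (1.0 - F_left[li]) / S_left[li], 0.0
                ) * dGamma
            comp1_pool = np.cumsum(g1_pool * haz1)

            # g2 on the group-l grid (all-cause martingale, group NA hazard)
            c_u = c_fun(uniq)
            with np.errstate(divide="ignore", invalid="ignore"):
                g2 = np.where(at_risk > 0, (1.0 - f_prev) * c_u / at_risk, 0.0)
                dLall = np.where(at_risk > 0, d_all / at_risk, 0.0)
            comp2 = np.cumsum(g2 * dLall)

            idx_T = np.searchsorted(uniq, tg)  # tg are exactly grid values
            # pooled-grid lookup: number of pooled event times <= T_i
            idx_P = np.searchsorted(ev_times, tg, side="right") - 1
            comp1_at_T = np.where(idx_P >= 0, comp1_pool[np.clip(idx_P, 0, None)], 0.0)
            pos_own = np.searchsorted(ev_times, tg)
            own_ok = (eg == cause) & (pos_own < D)
            own1 = np.zeros(len(tg))
            own1[own_ok] = g1_pool[pos_own[own_ok]]
            own2 = np.where(eg != 0, g2[idx_T], 0.0)
            h = own1 - comp1_at_T - (own2 - comp2[idx_T])
            H[m, ji] += h

    z = z_full[: k - 1]
    V = H.T @ H
    try:
        stat = float(z @ np.linalg.solve(V, z))
    except np.linalg.LinAlgError:
        stat = 0.0
    stat = max(stat, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return GrayTestResult(cause=int(cause), statistic=stat, df=df, p_value=p)
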