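"""Censored-survival statistics implemented from primitives.

The endpoint throughout is time to distant metastasis in months, right
censored at last follow-up.  Four estimators are provided:

* Kaplan-Meier product-limit curves (:func:`km_estimate`),
* the two-sample log-rank test (:func:`logrank_test`),
* Cox proportional-hazards regression by Newton-Raphson on the partial
  likelihood, Efron or Breslow handling of tied event times
  (:func:`cox_fit`), and
* time-dependent (cumulative cases / dynamic controls) ROC curves and AUC
  for a continuous marker, with Kaplan-Meier plug-in estimation of the
  conditional probabilities so that censored subjects contribute
  (:func:`td_roc`).

For the time-dependent ROC at horizon t, a "case" is a subject with an
event by t and a "control" a subject event-free beyond t.  With S the
overall survival function and S(c, t) = P(X > c, T > t) the joint
survivor function of marker and time,

    sensitivity(c, t) = [P(X > c) - S(c, t)] / [1 - S(t)]
    specificity(c, t) = 1 - S(c, t) / S(t)

The default estimator plugs in P_hat(X > c) * S_hat_{X>c}(t) for S(c, t),
with S_hat_{X>c} the Kaplan-Meier curve within the subgroup {X > c}; a
nearest-neighbor smoothed variant (``method="nne"``) replaces the subgroup
Kaplan-Meier with kernel-weighted conditional survival curves.  The KM
plug-in can stray outside [0, 1] under heavy censoring, so estimates are
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateCutpoint,
    DegenerateGroups,
    EmptyCohort,
    NoEventsByHorizon,
    NonConvergence,
    NonIdentifiable,
    UndefinedSurvival,
)

DEFAULT_HORIZONS = (36.0, 48.0, 60.0, 80.0, 96.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    at_risk: np.ndarray       # n_j at each event time
    n_events: np.ndarray      # d_j at each event time
    survival: np.ndarray      # S(t_j)
    n_total: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step evaluation; S(t) = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, weights=None) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted as at risk at that time
    (the standard censored-after-events tie convention).  Optional
    non-negative ``weights`` give the kernel-weighted curve used by the
    nearest-neighbor ROC variant.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise EmptyCohort("Kaplan-Meier needs >= 1 record")
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)

    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    total = float(w.sum())
    # at-risk weight just before each time = total minus weight of earlier exits
    cum_before = np.concatenate([[0.0], np.cumsum(w)[:-1]])
    uniq, first_idx = np.unique(t, return_index=True)
    d = np.zeros(uniq.size)
    n = np.zeros(uniq.size)
    grp = np.searchsorted(uniq, t)
    np.add.at(d, grp, w * e)
    n = total - cum_before[first_idx]

    has_event = d > 0
    et, dj, nj = uniq[has_event], d[has_event], n[has_event]
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - dj / nj)
    return KMCurve(event_times=et, at_risk=nj, n_events=dj,
                   survival=surv, n_total=int(t.size))


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    observed_a: float
    expected_a: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test with the hypergeometric variance.

    At each distinct pooled event time j with d_j events among n_j at risk
    (n_Aj of them in group A), the observed-minus-expected contribution is
    d_Aj - d_j n_Aj / n_j and the variance the hypergeometric
    d_j (n_Aj/n_j)(1 - n_Aj/n_j)(n_j - d_j)/(n_j - 1).  The statistic is
    chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise DegenerateGroups("both log-rank groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise DegenerateGroups("log-rank requires >= 1 event overall")

    pooled = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(pooled[pooled_e > 0])

    o_minus_e = 0.0
    var = 0.0
    observed_a = 0.0
    expected_a = 0.0
    for tj in event_times:
        at_risk = pooled >= tj
        n_j = at_risk.sum()
        n_aj = (at_risk & in_a).sum()
        is_event = (pooled == tj) & (pooled_e > 0)
        d_j = is_event.sum()
        d_aj = (is_event & in_a).sum()
        e_aj = d_j * n_aj / n_j
        o_minus_e += d_aj - e_aj
        observed_a += d_aj
        expected_a += e_aj
        if n_j > 1:
            var += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)

    statistic = 0.0 if var == 0 else o_minus_e ** 2 / var
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(statistic=float(statistic), p_value=p,
                         n_a=int(ta.size), n_b=int(tb.size),
                         observed_a=float(observed_a),
                         expected_a=float(expected_a))


def dichotomize_at_median(scores, cutpoint_scores=None):
    """Split a marker at the median of the designated cohort.

    ``cutpoint_scores`` defaults to ``scores`` itself (each patient group
    uses its own median as the cut point).  Values exactly equal to the cut
    point go to the low group, so the split is deterministic and
    order-independent.

    Returns ``(high_mask, cutpoint)`` where ``high_mask`` marks scores
    strictly above the cut point.

    Raises :class:`DegenerateCutpoint` if either group would be empty.
    """
    x = np.asarray(scores, dtype=float)
    own_median = cutpoint_scores is None
    ref = x if own_median else np.asarray(cutpoint_scores, dtype=float)
    if ref.size < 2:
        raise DegenerateCutpoint("cutpoint cohort needs >= 2 values")
    if np.ptp(ref) == 0:
        raise DegenerateCutpoint("all cutpoint-cohort scores are equal")
    cut = float(np.median(ref))
    high = x > cut
    # an externally supplied cut point may legitimately put every score on
    # one side; a cohort split at its own median must not
    if own_median and (high.all() or not high.any()):
        raise DegenerateCutpoint(
            f"median cut point {cut:.6g} leaves one group empty")
    return high, cut


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    Hazard ratios are exp(beta); for a continuous marker this is the
    multiplicative hazard change per unit score.  Wald 95% CIs use
    exp(beta -/+ 1.96 SE); the likelihood-ratio statistic compares the
    fitted model against the null (all-zero) model.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    wald_p: np.ndarray
    lrt_statistic: float
    lrt_p: float
    log_likelihood: float
    n_used: int
    n_events: int
    ties: str
    n_iter: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": list(self.terms),
            "coef": self.beta,
            "se": self.se,
            "hr": self.hazard_ratio,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "wald_p": self.wald_p,
            "n_used": self.n_used,
        })


def _cox_loglik_derivs(beta, t_desc, e_desc, x_desc, ties):
    """Log partial likelihood, gradient and Hessian (negative definite part).

    Rows are sorted by descending time so every risk set is a prefix.
    """
    eta = x_desc @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x_desc, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x_desc[:, :, None] * x_desc[:, None, :]),
                   axis=0)

    ll = 0.0
    grad = np.zeros(beta.size)
    hess = np.zeros((beta.size, beta.size))

    # block boundaries of equal times in the descending-sorted arrays
    n = t_desc.size
    block_start = 0
    while block_start < n:
        block_end = block_start
        while block_end + 1 < n and t_desc[block_end + 1] == t_desc[block_start]:
            block_end += 1
        ev = np.flatnonzero(e_desc[block_start:block_end + 1] > 0) + block_start
        m = ev.size
        if m > 0:
            r0, r1, r2 = s0[block_end], s1[block_end], s2[block_end]
            ll += float(eta[ev].sum())
            grad += x_desc[ev].sum(axis=0)
            if ties == "efron" and m > 1:
                t0 = w[ev].sum()
                t1 = (w[ev, None] * x_desc[ev]).sum(axis=0)
                t2 = (w[ev, None, None]
                      * (x_desc[ev, :, None] * x_desc[ev, None, :])).sum(axis=0)
                for l in range(m):
                    f = l / m
                    d0 = r0 - f * t0
                    d1 = r1 - f * t1
                    d2 = r2 - f * t2
                    ll -= np.log(d0)
                    grad -= d1 / d0
                    hess += d2 / d0 - np.outer(d1, d1) / d0 ** 2
            else:  # breslow, or a single event
                ll -= m * np.log(r0)
                grad -= m * r1 / r0
                hess += m * (r2 / r0 - np.outer(r1, r1) / r0 ** 2)
        block_start = block_end + 1
    return ll, grad, hess


def cox_partial_loglik(beta, times, events, x, ties="efron") -> float:
    """Log partial likelihood at an arbitrary coefficient vector.

    Exposed so independent checks (grid search, profile curves) can probe
    the same objective the fitter maximizes.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    xm = np.atleast_2d(np.asarray(x, float))
    if xm.shape[0] != t.size:
        xm = xm.T
    order = np.argsort(-t, kind="stable")
    ll, _, _ = _cox_loglik_derivs(np.asarray(beta, float),
                                  t[order], e[order], xm[order], ties)
    return ll


def cox_fit(data: pd.DataFrame, terms, time_col="time_months",
            event_col="event", ties="efron", max_iter=100,
            tol=1e-9) -> CoxFit:
    """Fit a (uni- or multivariate) Cox proportional-hazards model.

    Rows with a missing value in any requested term, the time or the event
    column are dropped (complete-case, per analysis).  Newton-Raphson with
    step-halving maximizes the partial likelihood; convergence is declared
    when the log partial likelihood changes by less than ``tol``.

    Raises
    ------
    NonIdentifiable
        No events among complete cases, or a term constant across them.
    NonConvergence
        Newton-Raphson did not converge within ``max_iter`` iterations.
    """
    terms = tuple(terms) if not isinstance(terms, str) else (terms,)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    cols = [time_col, event_col, *terms]
    sub = data[cols].dropna()
    t = sub[time_col].to_numpy(float)
    e = sub[event_col].to_numpy(float)
    x = sub[list(terms)].to_numpy(float)
    n_events = int(e.sum())
    if t.size == 0 or n_events == 0:
        raise NonIdentifiable("no events among complete cases")
    for j, name in enumerate(terms):
        if np.ptp(x[:, j]) == 0:
            raise NonIdentifiable(f"term {name!r} is constant across complete cases")

    order = np.argsort(-t, kind="stable")
    td, ed, xd = t[order], e[order], x[order]

    beta = np.zeros(len(terms))
    ll, grad, hess = _cox_loglik_derivs(beta, td, ed, xd, ties)
    ll0 = ll
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiable("singular information matrix") from exc
        # step-halving on decrease of the objective
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            new_ll, new_grad, new_hess = _cox_loglik_derivs(candidate, td, ed, xd, ties)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise NonConvergence("step-halving failed to improve the likelihood")
        delta = new_ll - ll
        beta, ll, grad, hess = candidate, new_ll, new_grad, new_hess
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise NonConvergence(f"no convergence in {max_iter} iterations")

    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(z))
    lrt = 2 * (ll - ll0)
    lrt_p = float(stats.chi2.sf(lrt, df=len(terms)))
    with np.errstate(over="ignore"):  # huge SE on tiny fits -> CI bound inf
        hr, ci_lo, ci_hi = (np.exp(beta), np.exp(beta - 1.96 * se),
                            np.exp(beta + 1.96 * se))
    return CoxFit(terms=terms, beta=beta, se=se,
                  hazard_ratio=hr,
                  ci_lower=ci_lo,
                  ci_upper=ci_hi,
                  wald_p=wald_p,
                  lrt_statistic=float(lrt), lrt_p=lrt_p,
                  log_likelihood=float(ll),
                  n_used=int(t.size), n_events=n_events,
                  ties=ties, n_iter=n_iter)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TdROC:
    """Cumulative/dynamic ROC of a continuous marker at one horizon."""

    horizon: float
    cutpoints: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    fpr: np.ndarray  # ROC abscissae including the (0,0)/(1,1) corners
    tpr: np.ndarray
    auc: float
    n_used: int
    method: str


def roc_auc(fpr, tpr) -> float:
    """Trapezoidal ROC area over points sorted by false-positive rate."""
    f = np.asarray(fpr, float)
    t = np.asarray(tpr, float)
    order = np.lexsort((t, f))
    return float(np.trapezoid(t[order], f[order]))


def _joint_survivor_km(times, events, marker, cutpoints, horizon):
    """S_hat(c, t) by the subgroup Kaplan-Meier plug-in."""
    out = np.empty(cutpoints.size)
    for i, c in enumerate(cutpoints):
        above = marker > c
        p_above = above.mean()
        if p_above == 0:
            out[i] = 0.0
            continue
        km_above = km_estimate(times[above], events[above])
        out[i] = p_above * km_above.survival_at(horizon)
    return out


def _joint_survivor_nne(times, events, marker, cutpoints, horizon, span):
    """S_hat(c, t) by nearest-neighbor kernel-weighted conditional survival.

    Each subject's conditional curve S(t | X = x_i) is a weighted
    Kaplan-Meier over the subjects whose marker percentile lies within
    span/2 of x_i's; the joint survivor is the average of those curves over
    {x_i > c}.  Unlike the raw subgroup plug-in this yields a proper
    bivariate survivor estimate.
    """
    n = times.size
    ranks = stats.rankdata(marker, method="average") / n
    cond = np.empty(n)
    half = span / 2.0
    for i in range(n):
        w = (np.abs(ranks - ranks[i]) <= half).astype(float)
        cond[i] = km_estimate(times, events, weights=w).survival_at(horizon)
    out = np.empty(cutpoints.size)
    for j, c in enumerate(cutpoints):
        above = marker > c
        out[j] = cond[above].sum() / n if above.any() else 0.0
    return out


def td_roc(times, events, marker, horizon, method="km", span=0.25) -> TdROC:
    """Time-dependent ROC for censored survival data at one horizon.

    Cases are subjects with events by the horizon (cumulative), controls
    those event-free beyond it (dynamic); Kaplan-Meier plug-ins estimate
    the conditional probabilities so censored subjects are handled.
    ``method="km"`` (default) uses subgroup Kaplan-Meier curves;
    ``method="nne"`` uses nearest-neighbor smoothing with percentile
    ``span``.  Sensitivity and specificity are clipped to [0, 1].

    Raises
    ------
    NoEventsByHorizon
        If no event is observed at or before the horizon.
    UndefinedSurvival
        If the overall Kaplan-Meier survival at the horizon is zero.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, float)
    x = np.asarray(marker, float)
    keep = np.isfinite(t) & np.isfinite(e) & np.isfinite(x)
    t, e, x = t[keep], e[keep], x[keep]
    if t.size == 0:
        raise EmptyCohort("time-dependent ROC needs >= 1 record")
    if not (0 < horizon <= t.max()):
        raise ValueError(f"horizon {horizon} outside (0, max observed time]")
    if not np.any((t <= horizon) & (e > 0)):
        raise NoEventsByHorizon(f"no events by t = {horizon}")

    overall = km_estimate(t, e)
    s_t = overall.survival_at(horizon)
    if s_t <= 0:
        raise UndefinedSurvival(f"S({horizon}) = 0; specificity undefined")

    cutpoints = np.unique(x)
    if method == "km":
        s_ct = _joint_survivor_km(t, e, x, cutpoints, horizon)
    elif method == "nne":
        s_ct = _joint_survivor_nne(t, e, x, cutpoints, horizon, span)
    else:
        raise ValueError("method must be 'km' or 'nne'")

    p_above = np.array([(x > c).mean() for c in cutpoints])
    sens = np.clip((p_above - s_ct) / (1.0 - s_t), 0.0, 1.0)
    spec = np.clip(1.0 - s_ct / s_t, 0.0, 1.0)

    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = roc_auc(fpr, tpr)
    return TdROC(horizon=float(horizon), cutpoints=cutpoints,
                 sensitivity=sens, specificity=spec,
                 fpr=fpr, tpr=tpr, auc=auc,
                 n_used=int(t.size), method=method)


def auc_at_horizon(tdroc: TdROC) -> float:
    """Trapezoid area of the ROC, corners (0,0) and (1,1) included."""
    return roc_auc(tdroc.fpr, tdroc.tpr)


def horizon_scan(times, events, marker, horizons=DEFAULT_HORIZONS,
                 method="km") -> dict[float, float]:
    """AUC at several horizons; horizons failing preconditions map to NaN.

    Emitted alongside any single-horizon AUC because the choice of horizon
    is a modelling decision, not a property of the data.
    """
    out: dict[float, float] = {}
    for h in horizons:
        try:
            out[float(h)] = td_roc(times, events, marker, h, method=method).auc
        except (NoEventsByHorizon, UndefinedSurvival, ValueError):
            out[float(h)] = float("nan")
    return out
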