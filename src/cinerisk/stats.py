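"""Survival evaluation stack.

Concordance, bootstrap confidence intervals, Cox proportional-hazards
fits (own Newton-Raphson maximizer with Breslow/Efron ties, which also
powers the Fine-Gray subdistribution model via inverse-probability-of-
censoring weights), Kaplan-Meier and log-rank (via lifelines), continuous
net reclassification improvement, exact-Poisson incidence rates, baseline
group comparisons, and the classical two-proportion sample-size formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "CoxFit",
    "KMCurve",
    "concordance_index",
    "bootstrap_ci",
    "fit_cox",
    "fine_gray",
    "kaplan_meier",
    "log_rank_test",
    "nri_continuous",
    "incidence_rate",
    "sample_size_two_proportions",
    "dichotomize_at_quantile",
    "compare_baseline",
]


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def concordance_index(
    scores: Sequence[float], times: Sequence[float], event_flags: Sequence[int]
) -> tuple[float, int]:
    """Harrell's C between a risk score and censored event times.

    A pair is comparable when the ordering of the event times is
    determinable: the earlier subject had an event, or the times tie and
    exactly the first of the pair had an event.  A higher score on the
    earlier-event subject is concordant; tied scores count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores, times and event_flags must have equal length")
    if e.sum() == 0:
        raise ValueError("no events: no comparable pairs")
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    comparable = (ti < tj) & ei | ((ti == tj) & ei & ~ej)
    np.fill_diagonal(comparable, False)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    si, sj = s[:, None], s[None, :]
    concordant = int((comparable & (si > sj)).sum())
    tied = int((comparable & (si == sj)).sum())
    return (concordant + 0.5 * tied) / n_pairs, n_pairs


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    n_subjects: int,
    n_resamples: int = 100,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap over subjects.

    ``statistic`` receives an integer index array (with repeats under
    resampling).  Returns (point estimate on the full sample, 2.5th,
    97.5th percentile of the resampled statistic).  A resample on which
    the statistic fails is redrawn, up to 10 retries.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(np.arange(n_subjects)))
    values = []
    for _ in range(n_resamples):
        for attempt in range(10):
            idx = rng.integers(0, n_subjects, size=n_subjects)
            try:
                values.append(float(statistic(idx)))
                break
            except Exception as exc:  # noqa: BLE001 - resample-level retry by contract
                warnings.warn(f"bootstrap resample failed (attempt {attempt + 1}): {exc}")
        else:
            raise RuntimeError("bootstrap statistic failed on 10 consecutive resamples")
    lower, upper = np.percentile(values, [2.5, 97.5])
    return estimate, float(lower), float(upper)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Fitted proportional-hazards coefficients with Wald inference.

    ``ci_95`` is on the hazard-ratio scale, ``p_values`` are two-sided
    Wald tests; for the Fine-Gray model the entries are subdistribution
    hazard ratios.
    """

    names: list[str]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    se: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    log_likelihood: float
    n_iter: int

    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.names])


class ConvergenceError(RuntimeError):
    pass


def _newton_maximize(
    nll_grad_hess: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
    p: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    beta = np.zeros(p)
    nll, grad, hess = nll_grad_hess(beta)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            return beta, hess, -nll, it
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from None
        alpha = 1.0
        for _ in range(30):
            cand = beta - alpha * step
            nll_new, grad_new, hess_new = nll_grad_hess(cand)
            if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                break
            alpha /= 2.0
        else:
            raise ConvergenceError("step halving failed to reduce the negative log-likelihood")
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 100:
            raise ConvergenceError(
                "coefficients diverging (monotone likelihood / perfect separation?)"
            )
    if np.max(np.abs(grad)) < 1e-4:  # close enough but flag slow convergence
        warnings.warn("Newton-Raphson hit the iteration cap with a small residual gradient")
        return beta, hess, -nll, max_iter
    raise ConvergenceError("Newton-Raphson failed to converge in 100 iterations")


def _cox_nll_grad_hess(
    beta: np.ndarray,
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # location invariance; stabilises exp
    w = np.exp(eta)
    order = np.argsort(times, kind="stable")[::-1]  # descending time
    Xs, ws, ts, es = X[order], w[order], times[order], events[order].astype(bool)
    cum_w = np.cumsum(ws)
    cum_wx = np.cumsum(ws[:, None] * Xs, axis=0)
    cum_wxx = np.cumsum(ws[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    nll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        D = np.arange(i, j)[es[i:j]]
        if D.size:
            d = D.size
            S0, S1, S2 = cum_w[j - 1], cum_wx[j - 1], cum_wxx[j - 1]
            xD, wD = Xs[D], ws[D]
            nll -= float(np.sum(np.log(wD)))
            grad -= xD.sum(axis=0)
            if ties == "breslow":
                nll += d * np.log(S0)
                m1 = S1 / S0
                grad += d * m1
                hess += d * (S2 / S0 - np.outer(m1, m1))
            elif ties == "efron":
                s0d = wD.sum()
                s1d = (wD[:, None] * xD).sum(axis=0)
                s2d = (wD[:, None, None] * (xD[:, :, None] * xD[:, None, :])).sum(axis=0)
                for ell in range(d):
                    f = ell / d
                    S0l = S0 - f * s0d
                    S1l = S1 - f * s1d
                    S2l = S2 - f * s2d
                    nll += np.log(S0l)
                    m1 = S1l / S0l
                    grad += m1
                    hess += S2l / S0l - np.outer(m1, m1)
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return nll, grad, hess


def _wald_fit(
    beta: np.ndarray, hess: np.ndarray, loglik: float, names: list[str], n_iter: int
) -> CoxFit:
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    # under a monotone likelihood the gradient vanishes at an arbitrarily
    # large coefficient with an even larger standard error: flag it
    degenerate = (np.abs(beta) > 10) & (se > np.abs(beta))
    if degenerate.any():
        bad = [names[int(i)] for i in np.flatnonzero(degenerate)]
        raise ConvergenceError(
            f"monotone likelihood (perfect separation?) for coefficient(s) {bad}"
        )
    z = sps.norm.ppf(0.975)
    coef = dict(zip(names, beta.tolist()))
    return CoxFit(
        names=names,
        coefficients=coef,
        hazard_ratios={k: float(np.exp(v)) for k, v in coef.items()},
        se=dict(zip(names, se.tolist())),
        ci_95={
            nme: (float(np.exp(b - z * s)), float(np.exp(b + z * s)))
            for nme, b, s in zip(names, beta, se)
        },
        p_values={
            nme: float(2 * sps.norm.sf(abs(b / s))) for nme, b, s in zip(names, beta, se)
        },
        log_likelihood=loglik,
        n_iter=n_iter,
    )


def fit_cox(
    covariate_matrix: np.ndarray,
    times: Sequence[float],
    event_flags: Sequence[int],
    ties: str = "efron",
    names: list[str] | None = None,
) -> CoxFit:
    """Maximum-partial-likelihood Cox fit with Wald CIs and p-values.

    Newton-Raphson from beta = 0, converged when the gradient max-norm
    drops below 1e-8 (at most 100 iterations).  Perfect separation
    (monotone likelihood) raises :class:`ConvergenceError`.
    """
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if X.shape[0] == 1 and len(times) > 1:
        X = X.T
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if X.shape[0] != len(t) or len(t) != len(e):
        raise ValueError("covariate matrix, times and event_flags must align")
    if e.sum() == 0:
        raise ValueError("no events")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column")
    names = names or [f"x{k}" for k in range(X.shape[1])]
    beta, hess, loglik, n_iter = _newton_maximize(
        lambda b: _cox_nll_grad_hess(b, X, t, e, ties), X.shape[1]
    )
    return _wald_fit(beta, hess, loglik, names, n_iter)


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazards
# ---------------------------------------------------------------------------


def _censoring_survival(times: np.ndarray, event_codes: np.ndarray):
    """Left-continuous Kaplan-Meier of the censoring distribution, G(t-) = P(C >= t)."""
    cens = (event_codes == 0).astype(int)
    uniq = np.unique(times)
    at_risk = np.array([(times >= u).sum() for u in uniq], dtype=float)
    d_cens = np.array([((times == u) & (cens == 1)).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - d_cens / at_risk)

    def G(t: np.ndarray) -> np.ndarray:
        # value just before t: product over censor times strictly < t
        idx = np.searchsorted(uniq, t, side="left") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return np.maximum(out, 1e-12)

    return G


def fine_gray(
    covariate_matrix: np.ndarray,
    times: Sequence[float],
    event_codes: Sequence[int],
    names: list[str] | None = None,
) -> CoxFit:
    """Fine-Gray model for the subdistribution hazard of the primary event.

    Subjects with a competing event (code 2) remain in later risk sets,
    down-weighted by the Kaplan-Meier censoring survival ratio
    G(t-)/G(s-) where s is their competing-event time.  Reduces exactly to
    the Breslow Cox fit when no competing events exist.  Wald inference
    uses the naive inverse information (coefficients are the estimator's;
    see the methods note for the variance caveat).
    """
    X = np.atleast_2d(np.asarray(covariate_matrix, dtype=float))
    if X.shape[0] == 1 and len(times) > 1:
        X = X.T
    t = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=int)
    if not set(np.unique(codes)) <= {0, 1, 2}:
        raise ValueError("event codes must be in {0, 1, 2}")
    if (codes == 1).sum() == 0:
        raise ValueError("no primary events")
    n, p = X.shape
    names = names or [f"x{k}" for k in range(p)]

    G = _censoring_survival(t, codes)
    event_times = np.unique(t[codes == 1])
    Gt = G(event_times)
    Gs = G(t)  # per-subject G(s-), used for competing-event subjects

    # risk-set membership and IPCW weight per (event time u, subject j)
    member = np.zeros((len(event_times), n))
    for k, u in enumerate(event_times):
        natural = t >= u
        carried = (codes == 2) & (t < u)
        member[k, natural] = 1.0
        member[k, carried] = Gt[k] / Gs[carried]

    def nll_grad_hess(beta: np.ndarray):
        eta = X @ beta
        eta = eta - eta.max()
        w = np.exp(eta)
        nll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
        for k, u in enumerate(event_times):
            D = np.flatnonzero((t == u) & (codes == 1))
            mw = member[k] * w
            S0 = mw.sum()
            S1 = mw @ X
            S2 = (mw[:, None] * X).T @ X
            m1 = S1 / S0
            d = len(D)
            nll += d * np.log(S0) - float(np.sum(np.log(w[D])))
            grad += d * m1 - X[D].sum(axis=0)
            hess += d * (S2 / S0 - np.outer(m1, m1))
        return nll, grad, hess

    beta, hess, loglik, n_iter = _newton_maximize(nll_grad_hess, p)
    return _wald_fit(beta, hess, loglik, names, n_iter)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank (lifelines-backed)
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve with a 95% confidence band."""

    event_times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def kaplan_meier(times: Sequence[float], event_flags: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate with the exponential-Greenwood (log(-log)) band."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if len(t) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter().fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    lo = np.nan_to_num(ci.iloc[:, 0].to_numpy(dtype=float), nan=1.0)
    hi = np.nan_to_num(ci.iloc[:, 1].to_numpy(dtype=float), nan=1.0)
    lo, hi = np.minimum(lo, surv), np.maximum(hi, surv)
    n_at_risk = np.array([(t >= u).sum() for u in grid], dtype=int)
    return KMCurve(event_times=grid, survival=surv, ci_lower=lo, ci_upper=hi, n_at_risk=n_at_risk)


def log_rank_test(groups: list[tuple[Sequence[float], Sequence[int]]]) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with k-1 df."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    times = np.concatenate([np.asarray(g[0], dtype=float) for g in groups])
    events = np.concatenate([np.asarray(g[1], dtype=int) for g in groups])
    if events.sum() == 0:
        raise ValueError("no events in any group")
    labels = np.concatenate([np.full(len(g[0]), k) for k, g in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Reclassification, incidence, design, splits, baseline tests
# ---------------------------------------------------------------------------


def nri_continuous(
    old_scores: Sequence[float], new_scores: Sequence[float], event_flags: Sequence[int]
) -> float:
    """Category-free net reclassification improvement of new over old scores."""
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    e = np.asarray(event_flags, dtype=bool)
    if not (len(old) == len(new) == len(e)):
        raise ValueError("length mismatch")
    if e.all() or not e.any():
        raise ValueError("need both event and non-event subjects")
    up, down = new > old, new < old
    nri_events = up[e].mean() - down[e].mean()
    nri_nonevents = down[~e].mean() - up[~e].mean()
    return float(nri_events + nri_nonevents)


def incidence_rate(
    n_events: int, person_years: float
) -> tuple[float, tuple[float, float]]:
    """Events per 100 person-years with an exact Poisson 95% CI."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    scale = 100.0 / person_years
    rate = n_events * scale
    lower = 0.0 if n_events == 0 else sps.chi2.ppf(0.025, 2 * n_events) / 2 * scale
    upper = sps.chi2.ppf(0.975, 2 * (n_events + 1)) / 2 * scale
    return rate, (lower, upper)


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.90
) -> tuple[int, int]:
    """Classical two-sided two-sample proportion sample size, equal allocation.

    n/group = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} sqrt(p1 q1 + p2 q2))^2
              / (p1 - p2)^2, rounded up.
    """
    for name, v in (("p1", p1), ("p2", p2), ("alpha", alpha), ("power", power)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be strictly in (0, 1); got {v}")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    pbar = (p1 + p2) / 2
    num = (z_a * np.sqrt(2 * pbar * (1 - pbar)) + z_b * np.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n_per_group = ceil(num / (p1 - p2) ** 2)
    return n_per_group, 2 * n_per_group


def dichotomize_at_quantile(scores: Sequence[float], q: float = 0.5) -> np.ndarray:
    """Label subjects 'low' (score <= q-quantile, linear interpolation) or 'high'."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty scores")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    cutoff = np.quantile(s, q)
    return np.where(s <= cutoff, "low", "high")


def compare_baseline(
    sample_a: Sequence, sample_b: Sequence, kind: str = "continuous_nonparametric"
) -> float:
    """Two-group baseline comparison p-value.

    ``categorical``: Pearson chi-square on the label contingency table;
    ``continuous_parametric``: Student's two-sample t-test;
    ``continuous_nonparametric``: two-sided Mann-Whitney U.
    """
    a, b = list(sample_a), list(sample_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if kind == "categorical":
        table = pd.crosstab(
            pd.Series(["a"] * len(a) + ["b"] * len(b)), pd.Series(a + b)
        ).to_numpy()
        if table.shape[1] < 2:
            raise ValueError("degenerate contingency table: single category")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p)
    if kind == "continuous_parametric":
        return float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    if kind == "continuous_nonparametric":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown comparison kind {kind!r}")
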