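"""Survival machinery: product-limit curves, log-rank tests, proportional
hazards fits, maximally selected cutpoints and IPCW time-dependent AUC.

The product-limit estimator and the multi-group log-rank statistic are
implemented directly (they are also building blocks of the cutpoint
search and the censoring weights); multivariate proportional-hazards
fitting is delegated to lifelines (Efron ties). Unit tests cross-check
the hand-built estimators against lifelines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats as sps

from .stats import TestResult, bh_adjust

__all__ = [
    "KmCurve",
    "CoxFit",
    "CutpointResult",
    "TdRocResult",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "partial_log_likelihood",
    "optimal_cutpoint",
    "td_auc",
    "survival_by_groups",
]

DAYS_PER_YEAR = 365.25


def _check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0) or not np.isfinite(time).all():
        raise ValueError("times must be positive and finite")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KmCurve:
    """Product-limit survival curve with Greenwood variance.

    ``survival[i]`` is the estimate just after ``event_times[i]``.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation of S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        out = np.where(idx >= 0, np.concatenate([[1.0], self.survival])[idx + 1], 1.0)
        return out

    def survival_before(self, t) -> np.ndarray:
        """Left-continuous evaluation S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="left") - 1
        return np.where(idx >= 0, np.concatenate([[1.0], self.survival])[idx + 1], 1.0)


def km_fit(time, event) -> KmCurve:
    """Kaplan-Meier product-limit fit.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times;
    Greenwood's formula supplies the pointwise variance. With no events
    the curve is identically 1 (warned, not fatal).
    """
    time, event = _check_time_event(time, event)
    if event.sum() == 0:
        warnings.warn("no events observed; survival curve is identically 1", stacklevel=2)
        return KmCurve(
            event_times=np.array([]),
            at_risk=np.array([], dtype=int),
            events=np.array([], dtype=int),
            survival=np.array([]),
            greenwood_var=np.array([]),
            n=time.size,
        )
    uniq = np.unique(time[event == 1])
    # at risk: subjects with observed time >= t
    sorted_all = np.sort(time)
    n_at_risk = time.size - np.searchsorted(sorted_all, uniq, side="left")
    d = np.array([int(np.sum((time == t) & (event == 1))) for t in uniq])
    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (n_at_risk * (n_at_risk - d))
        gw_terms[~np.isfinite(gw_terms)] = np.inf
        greenwood = np.where(surv > 0, surv**2 * np.cumsum(gw_terms), 0.0)
    return KmCurve(
        event_times=uniq,
        at_risk=n_at_risk,
        events=d,
        survival=surv,
        greenwood_var=greenwood,
        n=time.size,
    )


# ---------------------------------------------------------------------------
# log-rank


def _logrank_oe(time, event, codes, n_groups):
    """Observed/expected event counts and covariance for each group."""
    uniq = np.unique(time[event == 1])
    J = uniq.size
    n_g = np.empty((n_groups, J))
    d_g = np.zeros((n_groups, J))
    for g in range(n_groups):
        tg = np.sort(time[codes == g])
        n_g[g] = tg.size - np.searchsorted(tg, uniq, side="left")
        te = time[(codes == g) & (event == 1)]
        idx = np.searchsorted(uniq, te)
        np.add.at(d_g[g], idx, 1)
    n_tot = n_g.sum(axis=0)
    d_tot = d_g.sum(axis=0)
    expected = d_tot * n_g / n_tot
    O = d_g.sum(axis=1)
    E = expected.sum(axis=1)
    # hypergeometric covariance summed over event times
    with np.errstate(divide="ignore", invalid="ignore"):
        c = d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1, 1)
    p = n_g / n_tot  # (G, J)
    V = np.zeros((n_groups, n_groups))
    for a in range(n_groups):
        for b in range(n_groups):
            delta = 1.0 if a == b else 0.0
            V[a, b] = np.sum(c * p[a] * (delta - p[b]))
    return O, E, V


def logrank_test(time, event, group) -> TestResult:
    """Mantel-Haenszel log-rank test across >= 2 groups.

    The chi-square statistic uses the first g-1 groups' observed-minus-
    expected vector with its hypergeometric covariance; p from
    chi-square(g-1).
    """
    time, event = _check_time_event(time, event)
    group = np.asarray(group)
    labels, codes = np.unique(group, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts == 0).any():
        raise ValueError("every group needs at least one subject")
    if event.sum() == 0:
        return TestResult(0.0, 1.0, "logrank", time.size, df=labels.size - 1)
    O, E, V = _logrank_oe(time, event, codes, labels.size)
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, labels.size - 1)) if stat > 0 else 1.0
    return TestResult(stat, p, "logrank", time.size, df=labels.size - 1)


def _logrank_z(time, event, mask) -> float:
    """Standardized two-group log-rank statistic (group = mask vs rest)."""
    codes = mask.astype(int)
    O, E, V = _logrank_oe(time, event, codes, 2)
    v = V[0, 0]
    if v <= 0:
        return 0.0
    return float((O[0] - E[0]) / np.sqrt(v))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    """Proportional-hazards fit summary (Efron tie handling)."""

    summary: pd.DataFrame  # index: term; columns: beta, se, hr, ci_lo, ci_hi, p
    cov: pd.DataFrame
    log_likelihood: float
    converged: bool
    tie_method: str = "efron"
    n: int = 0
    warnings_: list[str] = field(default_factory=list)

    @property
    def betas(self) -> pd.Series:
        return self.summary["beta"]


def cox_fit(time, event, covariates: pd.DataFrame, tie_method: str = "efron") -> CoxFit:
    """Fit a proportional-hazards model via lifelines.

    Wald confidence intervals are computed on the log-hazard scale as
    exp(beta +/- 1.96 se). Non-convergence yields a flagged (NaN) fit
    rather than a silent result; |beta| > 20 triggers a separation
    warning.
    """
    if tie_method != "efron":
        raise ValueError("only Efron tie handling is supported")
    time, event = _check_time_event(time, event)
    covariates = pd.DataFrame(covariates).astype(float)
    if covariates.shape[0] != time.size:
        raise ValueError("covariates and survival data differ in length")
    if time.size <= covariates.shape[1]:
        raise ValueError("need more subjects than covariates")
    const = covariates.columns[covariates.nunique() <= 1]
    if len(const):
        raise ValueError(f"constant covariate(s): {const.tolist()}")
    df = covariates.copy()
    df["_time"] = time
    df["_event"] = event
    fitter = CoxPHFitter()
    msgs: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(df, duration_col="_time", event_col="_event")
        msgs = [str(w.message) for w in caught]
    except Exception as exc:  # lifelines ConvergenceError and friends
        nan = np.full(covariates.shape[1], np.nan)
        summary = pd.DataFrame(
            {"beta": nan, "se": nan, "hr": nan, "ci_lo": nan, "ci_hi": nan, "p": nan},
            index=covariates.columns,
        )
        return CoxFit(
            summary=summary,
            cov=pd.DataFrame(
                np.full((len(nan), len(nan)), np.nan),
                index=covariates.columns,
                columns=covariates.columns,
            ),
            log_likelihood=np.nan,
            converged=False,
            n=time.size,
            warnings_=[f"fit failed: {exc}"],
        )
    beta = fitter.params_
    se = fitter.standard_errors_
    z = beta / se
    p = 2 * sps.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_lo": np.exp(beta - 1.96 * se),
            "ci_hi": np.exp(beta + 1.96 * se),
            "p": p,
        }
    )
    if (np.abs(beta) > 20).any():
        msgs.append("possible separation: |beta| > 20")
        warnings.warn("possible separation: |beta| > 20", stacklevel=2)
    return CoxFit(
        summary=summary,
        cov=fitter.variance_matrix_,
        log_likelihood=float(fitter.log_likelihood_),
        converged=True,
        n=time.size,
        warnings_=msgs,
    )


def partial_log_likelihood(time, event, x, beta: float, ties: str = "efron") -> float:
    """Univariate Cox partial log-likelihood at a given coefficient.

    Supports Efron and Breslow tie handling; used for diagnostics and
    for checking tie-free equivalence of the two approximations.
    """
    time, event = _check_time_event(time, event)
    x = np.asarray(x, dtype=float)
    eta = beta * x
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        risk = time >= t
        d = int(deaths.sum())
        sum_eta = float(eta[deaths].sum())
        s0 = float(w[risk].sum())
        d0 = float(w[deaths].sum())
        if ties == "breslow":
            ll += sum_eta - d * np.log(s0)
        elif ties == "efron":
            for l in range(d):
                ll += 0.0 if l else sum_eta
                ll -= np.log(s0 - (l / d) * d0)
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return ll


# ---------------------------------------------------------------------------
# maximally selected cutpoint


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float  # |standardized log-rank| at the chosen cutoff
    n_low: int
    n_high: int
    minprop: float
    p_naive: float
    p_permutation: float | None = None


def optimal_cutpoint(
    marker,
    time,
    event,
    minprop: float = 0.1,
    n_permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker.

    Evaluates the standardized two-group log-rank statistic at every
    observed marker value whose induced split leaves both groups with at
    least ``ceil(minprop * n)`` subjects, and returns the |z|-maximizing
    cutoff (low group: marker <= cutoff).

    ``p_naive`` is the unadjusted two-sided p of the chosen statistic;
    it ignores the selection over cutoffs and is anti-conservative. If
    ``n_permutations`` > 0 a permutation-corrected p (distribution of
    the maximal |z| under marker permutation) is reported alongside.
    """
    time, event = _check_time_event(time, event)
    marker = np.asarray(marker, dtype=float)
    n = marker.size
    min_n = int(np.ceil(minprop * n))

    def _max_z(mk):
        cuts = np.unique(mk)[:-1]  # splitting at max leaves empty high group
        best = (None, 0.0)
        for c in cuts:
            low = mk <= c
            nl = int(low.sum())
            if nl < min_n or n - nl < min_n:
                continue
            z = abs(_logrank_z(time, event, low))
            if best[0] is None or z > best[1]:
                best = (c, z)
        return best

    cutoff, zmax = _max_z(marker)
    if cutoff is None:
        raise ValueError("no admissible cutoff satisfies the minprop constraint")
    p_naive = float(2 * sps.norm.sf(zmax))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            _, z = _max_z(rng.permutation(marker))
            if z >= zmax:
                exceed += 1
        p_perm = (exceed + 1) / (n_permutations + 1)
    low = marker <= cutoff
    return CutpointResult(
        cutoff=float(cutoff),
        statistic=zmax,
        n_low=int(low.sum()),
        n_high=int(n - low.sum()),
        minprop=minprop,
        p_naive=p_naive,
        p_permutation=p_perm,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC / AUC


@dataclass
class TdRocResult:
    """Cumulative-case / dynamic-control AUC(t) at each horizon."""

    horizons: list[float]  # same unit as `time`
    auc: dict[float, float]
    n_cases: dict[float, int]
    n_controls: dict[float, int]
    flipped: bool
    dropped_horizons: list[float] = field(default_factory=list)


def td_auc(
    marker,
    time,
    event,
    horizons_years=(1.0, 2.0, 3.0, 4.0),
    time_in_days: bool = True,
    orient: bool = False,
) -> TdRocResult:
    """IPCW time-dependent AUC under the higher-marker = higher-risk
    convention.

    Cases at horizon t are subjects with an observed event by t;
    controls are subjects still under observation beyond t. Case pairs
    are weighted by the inverse of the censoring-distribution survival
    G(T_i-) estimated by Kaplan-Meier on flipped event indicators
    (control weights are constant given t and cancel).

    Horizons beyond follow-up (no cases or no controls) are dropped with
    a warning. With ``orient=True`` the marker direction is flipped when
    the mean AUC is below 0.5, and the flip is recorded.
    """
    time, event = _check_time_event(time, event)
    marker = np.asarray(marker, dtype=float)
    horizons = [float(h) * (DAYS_PER_YEAR if time_in_days else 1.0) for h in horizons_years]
    cens_km = km_fit(time, 1 - event) if (1 - event).sum() > 0 else None

    def _auc_at(t, mk):
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            return None
        if cens_km is not None:
            g = cens_km.survival_before(time[cases])
            g = np.maximum(g, 1e-12)
            w = 1.0 / g
        else:
            w = np.ones(int(cases.sum()))
        mc = mk[cases][:, None]
        mn = mk[controls][None, :]
        conc = (mc > mn) + 0.5 * (mc == mn)
        num = float((w[:, None] * conc).sum())
        den = float(w.sum() * controls.sum())
        return num / den, int(cases.sum()), int(controls.sum())

    auc: dict[float, float] = {}
    ncase: dict[float, int] = {}
    nctrl: dict[float, int] = {}
    dropped: list[float] = []
    for t in horizons:
        res = _auc_at(t, marker)
        if res is None:
            dropped.append(t)
            warnings.warn(f"horizon {t} beyond follow-up; dropped", stacklevel=2)
            continue
        auc[t], ncase[t], nctrl[t] = res
    if not auc:
        raise ValueError("no horizon has both cases and controls")
    flipped = False
    if orient and np.mean(list(auc.values())) < 0.5:
        flipped = True
        auc = {t: 1.0 - a for t, a in auc.items()}
    return TdRocResult(
        horizons=list(auc),
        auc=auc,
        n_cases=ncase,
        n_controls=nctrl,
        flipped=flipped,
        dropped_horizons=dropped,
    )


# ---------------------------------------------------------------------------
# grouped survival


def survival_by_groups(time, event, labels) -> dict:
    """KM curve per group, global log-rank and BH-adjusted pairwise tests."""
    time, event = _check_time_event(time, event)
    labels = pd.Series(labels).reset_index(drop=True)
    if labels.size != time.size:
        raise ValueError("labels must cover all subjects")
    groups = sorted(labels.unique())
    curves = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in groups:
            m = (labels == g).to_numpy()
            curves[g] = km_fit(time[m], event[m])
    global_test = logrank_test(time, event, labels.to_numpy())
    pair_rows = []
    for a, b in itertools.combinations(groups, 2):
        m = labels.isin([a, b]).to_numpy()
        res = logrank_test(time[m], event[m], labels[m].to_numpy())
        pair_rows.append({"group_a": a, "group_b": b, "statistic": res.statistic, "p": res.p_value})
    pairwise = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "statistic", "p"])
    if len(pairwise):
        pairwise["p_adj"] = bh_adjust(pairwise["p"].to_numpy())
    return {"curves": curves, "global": global_test, "pairwise": pairwise}
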