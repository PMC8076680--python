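"""Survival machinery: Cox models, log-rank, Kaplan-Meier, lasso selection,
and time-dependent ROC.

``cox_fit`` is a Newton-Raphson maximiser of the Cox partial likelihood with
the Efron correction for tied event times (Breslow available).  The lasso
path is computed by the coordinate-descent solver of scikit-survival
(the glmnet analogue for Cox models); cross-validated deviance follows the
Verweij & Van Houwelingen leave-fold-out construction.  The time-dependent
ROC uses the cumulative-case / dynamic-control estimator with Kaplan-Meier
conditional survival, and picks the cutoff maximising the Youden index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .pairs import IRGPSignature, PairScoreMatrix, SignaturePair

__all__ = [
    "CoxFit",
    "LogrankResult",
    "LassoPath",
    "TimeDependentROC",
    "cox_fit",
    "logrank_test",
    "km_curve",
    "km_survival_at",
    "univariate_screen",
    "lasso_cox_select",
    "td_roc",
]

_Z95 = 1.959963984540054  # normal quantile for 95% intervals


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``summary`` has one row per covariate: coef, se, hr, ci_lower, ci_upper,
    p (Wald).  ``log_likelihood`` is the maximised log partial likelihood.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    n_iter: int

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]


def _efron_derivatives(beta, X, time, event, ties="efron"):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Rows must be sorted by descending time so risk-set sums are prefix
    sums.  Untied event times take a fully vectorised path; tied times
    fall back to a per-event-time loop with the Efron (or Breslow)
    correction.
    """
    n, p = X.shape
    eta = np.clip(X @ beta, -500, 500)
    theta = np.exp(eta)
    wx = theta[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    cs = np.cumsum(theta)
    csx = np.cumsum(wx, axis=0)
    csxx = np.cumsum(wxx.reshape(n, -1), axis=0).reshape(n, p, p)
    # last row of each tied-time block (rows sorted by descending time)
    ends = np.searchsorted(-time, -time, side="right") - 1
    ev = np.flatnonzero(event)
    if ev.size == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))

    if len(np.unique(time)) == n:  # no ties at all: vectorised path
        phi = cs[ends[ev]]
        zeta = csx[ends[ev]] / phi[:, None]
        ll = float(eta[ev].sum() - np.log(phi).sum())
        grad = X[ev].sum(axis=0) - zeta.sum(axis=0)
        hess = -(
            (csxx[ends[ev]] / phi[:, None, None]).sum(axis=0) - zeta.T @ zeta
        )
        return ll, grad, hess

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    _, starts, counts = np.unique(-time, return_index=True, return_counts=True)
    for s0, cnt in zip(starts, counts):
        block = np.arange(s0, s0 + cnt)
        d_idx = block[event[block].astype(bool)]
        d = d_idx.size
        if d == 0:
            continue
        end = s0 + cnt - 1
        s_r, z_r, q_r = cs[end], csx[end], csxx[end]
        s_d = theta[d_idx].sum()
        z_d = wx[d_idx].sum(axis=0)
        q_d = wxx[d_idx].sum(axis=0)
        ll += eta[d_idx].sum()
        grad += X[d_idx].sum(axis=0)
        for ell in range(d):
            f = ell / d if ties == "efron" else 0.0
            phi = s_r - f * s_d
            zeta = (z_r - f * z_d) / phi
            ll -= np.log(phi)
            grad -= zeta
            hess -= (q_r - f * q_d) / phi - np.outer(zeta, zeta)
    return ll, grad, hess


def cox_fit(
    time,
    event,
    covariates,
    names=None,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFit:
    """Maximum partial-likelihood Cox regression via Newton-Raphson.

    Parameters
    ----------
    time, event
        Follow-up times (> 0) and event indicators (1 event, 0 censored).
    covariates
        DataFrame or 2-d array, one row per subject.
    ties
        ``"efron"`` (default) or ``"breslow"`` tie correction.

    Raises
    ------
    ValidationError
        On a constant covariate ("degenerate covariate"), collinear
        covariates, or zero events.

    Notes
    -----
    Convergence: max |score| < ``tol`` or ``max_iter`` Newton steps (with
    step-halving).  A monotone likelihood (perfect separation) triggers a
    warning and the iteration cap.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(time)) != 1:
            X = X.T
        if names is None:
            names = [f"x{k}" for k in range(X.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie correction {ties!r}")
    n, p = X.shape
    if n != len(time) or n != len(event):
        raise ValidationError("time, event and covariates must align")
    if event.sum() < 1:
        raise ValidationError("at least one event is required")
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [names[k] for k in np.flatnonzero(const)]
        raise ValidationError("degenerate covariate (constant): " + ", ".join(bad))
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValidationError("collinear covariates: design matrix is rank deficient")

    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    beta = np.zeros(p)
    ll, grad, hess = _efron_derivatives(beta, Xs, ts, es, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new_beta = beta - step  # hess is negative definite
        new_ll, new_grad, new_hess = _efron_derivatives(new_beta, Xs, ts, es, ties)
        halves = 0
        while new_ll < ll and halves < 20:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _efron_derivatives(new_beta, Xs, ts, es, ties)
            halves += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        it = max_iter
    if np.max(np.abs(grad)) < tol:
        converged = True
    if not converged or np.max(np.abs(beta)) > 15:
        if np.max(np.abs(beta)) > 15:
            warnings.warn(
                "possible monotone partial likelihood (perfect separation); "
                "coefficients capped at the iteration limit",
                RuntimeWarning,
                stacklevel=2,
            )

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # infinite CI under separation is fine
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - _Z95 * se),
                "ci_upper": np.exp(beta + _Z95 * se),
                "p": pvals,
            },
            index=pd.Index(names, name="covariate"),
        )
    return CoxFit(
        summary=summary,
        log_likelihood=float(ll),
        n=n,
        n_events=int(event.sum()),
        converged=converged,
        n_iter=it,
    )


def breslow_loglik(beta, X, time, event) -> float:
    """Breslow-tie Cox log partial likelihood (used for CV deviance)."""
    beta = np.asarray(beta, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    order = np.argsort(-time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = np.clip(X @ beta, -500, 500)
    theta = np.exp(eta)
    cum = np.cumsum(theta)
    # risk-set total at each row: everyone with time >= this row's time
    # rows are sorted descending, ties share the full tied block
    idx = np.searchsorted(-time, -time, side="right") - 1
    risk = cum[idx]
    ev = event.astype(bool)
    return float(np.sum(eta[ev] - np.log(risk[ev])))


# ---------------------------------------------------------------------------
# Log-rank and Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray


def logrank_test(time, event, groups) -> LogrankResult:
    """Two-group log-rank test (O-E over event times, hypergeometric variance).

    ``groups`` must take exactly two values.  Returns the 1-df chi-square
    statistic and p-value; with no events the statistic is 0 and p is 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValidationError(
            f"log-rank requires exactly two groups, got {len(levels)}"
        )
    g1 = groups == levels[0]
    et = np.unique(time[event == 1])
    if et.size:
        ts = np.sort(time)
        t1s = np.sort(time[g1])
        ets = np.sort(time[event == 1])
        et1s = np.sort(time[g1 & (event == 1)])
        n_at = len(time) - np.searchsorted(ts, et, side="left")
        n1_at = g1.sum() - np.searchsorted(t1s, et, side="left")
        d = np.searchsorted(ets, et, side="right") - np.searchsorted(ets, et, side="left")
        d1 = np.searchsorted(et1s, et, side="right") - np.searchsorted(
            et1s, et, side="left"
        )
        o1 = float(d1.sum())
        e1 = float((d * n1_at / n_at).sum())
        ok = n_at > 1
        var = float(
            (
                d[ok] * (n_at[ok] - d[ok]) * n1_at[ok] * (n_at[ok] - n1_at[ok])
                / (n_at[ok] ** 2 * (n_at[ok] - 1))
            ).sum()
        )
    else:
        o1 = e1 = var = 0.0
    if var <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))
    o = np.array([o1, event.sum() - o1], dtype=float)
    e = np.array([e1, event.sum() - e1], dtype=float)
    return LogrankResult(chi2=float(chi2), p=p, observed=o, expected=e)


def km_curve(time, event, conf_level: float = 0.95) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood confidence bands.

    Returns a DataFrame indexed by event time with columns ``n_at_risk``,
    ``n_events``, ``survival``, ``ci_lower``, ``ci_upper``.  Times with no
    events do not change the estimate and are omitted.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 1:
        raise ValidationError("at least one subject required")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    s = 1.0
    gw = 0.0  # Greenwood sum d / (n (n - d))
    for t in np.unique(time[event == 1]):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
            half = z * s * np.sqrt(gw)
        else:
            half = 0.0
        rows.append(
            {
                "time": t,
                "n_at_risk": n,
                "n_events": d,
                "survival": s,
                "ci_lower": max(s - half, 0.0),
                "ci_upper": min(s + half, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "survival", "ci_lower", "ci_upper"]
    )
    return df.set_index("time")


def km_survival_at(time, event, t: float) -> float:
    """S(t) from the product-limit estimator (1.0 before the first event)."""
    curve = km_curve(time, event)
    if curve.empty:
        return 1.0
    past = curve.loc[curve.index <= t, "survival"]
    return float(past.iloc[-1]) if len(past) else 1.0


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------


def univariate_screen(
    pair_matrix: PairScoreMatrix,
    time,
    event,
    alpha: float = 0.05,
) -> tuple[PairScoreMatrix, pd.DataFrame]:
    """Keep pairs prognostic by BOTH univariate Cox and two-group log-rank.

    A pair survives when its Wald p-value from a single-covariate Cox fit
    and the log-rank p-value comparing indicator 0 vs 1 are each below
    ``alpha``.  Returns the restricted matrix and the full screening table
    (coef, cox_p, logrank_p, kept).

    Raises
    ------
    ValidationError
        When no pair survives (advising a larger alpha).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError("alpha must lie in (0, 1]")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    for k, (a, b) in enumerate(pair_matrix.pairs):
        x = pair_matrix.scores[k].astype(float)
        if np.ptp(x) == 0:  # degenerate after subsetting; cannot be prognostic
            rows.append((f"{a}|{b}", np.nan, 1.0, 1.0, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = cox_fit(time, event, x[:, None], names=["pair"])
        cox_p = float(fit.summary["p"].iloc[0])
        lr = logrank_test(time, event, x)
        kept = cox_p < alpha and lr.p < alpha
        rows.append((f"{a}|{b}", float(fit.summary["coef"].iloc[0]), cox_p, lr.p, kept))
    table = pd.DataFrame(
        rows, columns=["pair", "coef", "cox_p", "logrank_p", "kept"]
    ).set_index("pair")
    keep_idx = np.flatnonzero(table["kept"].to_numpy())
    if len(keep_idx) == 0:
        raise ValidationError(
            f"no pair passed univariate screening at alpha={alpha}; "
            "consider a larger alpha"
        )
    return pair_matrix.subset(keep_idx), table


# ---------------------------------------------------------------------------
# Lasso-penalised Cox with cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LassoPath:
    """Lasso-Cox regularisation path with cross-validated deviance.

    ``alphas`` decrease; ``coefs`` is (n_features, n_alphas).  ``cv_mean``
    and ``cv_se`` are the mean and standard error of the leave-fold-out
    deviance at each alpha; ``alpha_min`` minimises the mean and
    ``alpha_1se`` is the largest alpha within one standard error of it.
    """

    alphas: np.ndarray
    coefs: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    alpha_min: float
    alpha_1se: float
    selected_alpha: float
    feature_names: list[str]

    def coefs_at(self, alpha: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.alphas - alpha)))
        return self.coefs[:, k]


def _make_folds(n, k_folds, events, rng, max_tries=20):
    """Seeded fold assignment stratified by event status.

    Events and censored subjects are spread evenly across folds (the usual
    variance-reduction device for survival cross-validation); reshuffles
    with a warning if a training part would end up without events.
    """
    events = np.asarray(events).astype(bool)
    for attempt in range(max_tries):
        folds = np.empty(n, dtype=int)
        for mask in (events, ~events):
            idx = rng.permutation(np.flatnonzero(mask))
            folds[idx] = np.arange(len(idx)) % k_folds
        ok = all(
            events[folds != f].sum() >= 2 and events[folds == f].sum() >= 1
            for f in range(k_folds)
        )
        if ok:
            return folds
        warnings.warn(
            "a cross-validation fold had too few events; reshuffling",
            RuntimeWarning,
            stacklevel=3,
        )
    return folds


def lasso_cox_path(
    X: np.ndarray,
    time,
    event,
    feature_names,
    k_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
    alphas=None,
) -> LassoPath:
    """L1-penalised Cox path (coordinate descent) with k-fold CV deviance.

    The path is fitted on the full data over a log-spaced alpha grid whose
    largest value zeroes every coefficient.  For each fold, the model is
    refitted on the complement and the fold's deviance contribution is
    -2 [pl(all; beta) - pl(train; beta)] (Verweij & Van Houwelingen).
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    n = len(time)
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    if alphas is not None:  # explicit grid disables glmnet-style early stopping
        full.set_params(alphas=list(alphas))
    full.fit(X, y)
    alphas = np.asarray(full.alphas_)
    coefs = np.asarray(full.coef_)  # (p, n_alphas)
    # prepend an alpha above the grid maximum so the all-zero solution is explicit
    if np.abs(coefs[:, 0]).max() > 0:
        alphas = np.concatenate([[alphas[0] * 1.001], alphas])
        coefs = np.concatenate([np.zeros((coefs.shape[0], 1)), coefs], axis=1)

    rng = np.random.default_rng(seed)
    folds = _make_folds(n, k_folds, event, rng)
    dev = np.full((k_folds, len(alphas)), np.nan)
    for f in range(k_folds):
        tr = folds != f
        fit_f = CoxnetSurvivalAnalysis(l1_ratio=1.0, fit_baseline_model=False)
        fit_f.set_params(alphas=list(alphas))
        try:
            fit_f.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        except (ValueError, ArithmeticError) as exc:  # degenerate fold
            warnings.warn(f"fold {f} failed to fit ({exc}); skipped", RuntimeWarning)
            continue
        fold_alphas = np.asarray(fit_f.alphas_)
        fold_coefs = np.asarray(fit_f.coef_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fold_alphas - a)))
            beta = fold_coefs[:, jj]
            dev[f, j] = -2.0 * (
                breslow_loglik(beta, X, time, event)
                - breslow_loglik(beta, X[tr], time[tr], event[tr])
            )
    cv_mean = np.nanmean(dev, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(dev), axis=0).clip(min=1)
        )
    k_min = int(np.nanargmin(cv_mean))
    alpha_min = float(alphas[k_min])
    within = np.flatnonzero(cv_mean <= cv_mean[k_min] + cv_se[k_min])
    alpha_1se = float(alphas[within.min()]) if len(within) else alpha_min
    if selection == "min":
        selected = alpha_min
    elif selection == "1se":
        selected = alpha_1se
    else:
        raise ValidationError(f"unknown lambda selection rule {selection!r}")
    return LassoPath(
        alphas=alphas,
        coefs=coefs,
        cv_mean=cv_mean,
        cv_se=cv_se,
        alpha_min=alpha_min,
        alpha_1se=alpha_1se,
        selected_alpha=selected,
        feature_names=list(feature_names),
    )


def lasso_cox_select(
    pair_matrix: PairScoreMatrix,
    time,
    event,
    k_folds: int = 10,
    seed: int = 0,
    selection: str = "min",
) -> tuple[LassoPath, IRGPSignature]:
    """Select a gene-pair signature by cross-validated lasso Cox regression.

    Pairs with non-zero coefficients at the selected penalty become the
    signature (cutoff left unset).  Raises when the selected solution is
    all-zero ("no signal selected").
    """
    path = lasso_cox_path(
        pair_matrix.scores.T.astype(float),
        time,
        event,
        feature_names=pair_matrix.pair_labels,
        k_folds=k_folds,
        seed=seed,
        selection=selection,
    )
    beta = path.coefs_at(path.selected_alpha)
    nz = np.flatnonzero(beta != 0.0)
    if len(nz) == 0:
        raise ValidationError(
            "no signal selected: all lasso coefficients are zero at the "
            "cross-validated penalty"
        )
    sig_pairs = [
        SignaturePair(
            gene_a=pair_matrix.pairs[k][0],
            gene_b=pair_matrix.pairs[k][1],
            coefficient=float(beta[k]),
        )
        for k in nz
    ]
    return path, IRGPSignature(pairs=sig_pairs, cutoff=None)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------


@dataclass
class TimeDependentROC:
    """Cumulative-case / dynamic-control ROC at a fixed horizon.

    ``curve`` has one row per cutpoint with sensitivity and specificity;
    ``auc`` is the trapezoidal area and ``cutoff`` maximises the Youden
    index J = sensitivity + specificity - 1.
    """

    t_eval: float
    curve: pd.DataFrame
    auc: float
    cutoff: float
    youden: float


def td_roc(scores, time, event, t_eval: float = 365.0) -> TimeDependentROC:
    """Time-dependent ROC for a risk score at horizon ``t_eval`` (days).

    Cases are subjects with an event by ``t_eval``, controls those surviving
    past it; both probabilities are estimated under censoring with
    Kaplan-Meier conditional survival within score strata:

        sensitivity(c) = P(X > c) (1 - S(t | X > c)) / (1 - S(t))
        specificity(c) = P(X <= c) S(t | X <= c) / S(t)

    Cutpoints are midpoints between consecutive unique scores (plus open
    ends).  Raises when no event has occurred by ``t_eval``.
    """
    scores = np.asarray(pd.Series(scores), dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if t_eval <= 0 or t_eval > time.max():
        raise ValidationError(
            f"evaluation time {t_eval} outside observed follow-up (0, {time.max()}]"
        )
    s_t = km_survival_at(time, event, t_eval)
    if s_t >= 1.0:
        raise ValidationError("no cases at evaluation time: S(t) = 1")
    uniq = np.unique(scores)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n = len(scores)
    sens = np.empty(len(cuts))
    spec = np.empty(len(cuts))
    for i, c in enumerate(cuts):
        above = scores > c
        p_above = above.mean()
        if p_above > 0:
            s_above = km_survival_at(time[above], event[above], t_eval)
            sens[i] = p_above * (1.0 - s_above) / (1.0 - s_t)
        else:
            sens[i] = 0.0
        if p_above < 1:
            s_below = km_survival_at(time[~above], event[~above], t_eval)
            spec[i] = (1.0 - p_above) * s_below / s_t
        else:
            spec[i] = 0.0
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # snap float noise so vertical staircase segments share one x exactly
    fpr = np.round(1.0 - spec, 12)
    pts = np.array(list(zip(fpr, np.round(sens, 12))) + [(1.0, 1.0), (0.0, 0.0)])
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    curve = pd.DataFrame(
        {"cutpoint": cuts, "sensitivity": sens, "specificity": spec, "youden": j}
    )
    return TimeDependentROC(
        t_eval=float(t_eval),
        curve=curve,
        auc=auc,
        cutoff=float(cuts[best]),
        youden=float(j[best]),
    )
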