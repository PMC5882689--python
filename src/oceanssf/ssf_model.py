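"""Conditional logistic regression for matched 1:M step-selection strata.

The likelihood is the stratum-wise discrete-choice (softmax) form

    l(beta) = sum_strata [ beta'x_case - log sum_{j in stratum} exp(beta'x_j) ]

which conditions out any stratum-constant effect.  It is maximized by
Newton-Raphson from beta = 0 with step-halving, using the analytic
gradient sum(x_case - xbar_w) and Hessian -sum(weighted within-stratum
covariance), with log-sum-exp stabilization.  Wald standard errors come
from the inverse observed information at the optimum; p-values use the
normal approximation, matching the conventions under which matched
case-control step-selection results are conventionally reported.

The estimator follows the scikit-learn protocol (``fit(X, y,
groups=...)``, fitted attributes with trailing underscores,
``get_params``/``set_params``), so it composes with sklearn tooling;
:func:`fit_clogit` and :func:`backward_select` are the pipeline-facing
wrappers operating on step tables and term lists.  Interaction terms are
written ``"a:b"`` and multiply the named (typically scaled) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array


def _stratum_layout(groups: np.ndarray, y: np.ndarray):
    """Sort rows by stratum; return (order, starts, counts, case_positions)."""
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    counts = np.diff(np.r_[starts, len(g)])
    ys = y[order].astype(bool)
    n_cases = np.add.reduceat(ys.astype(int), starts)
    if np.any(n_cases != 1):
        bad = np.unique(g[np.repeat(n_cases != 1, counts)])[:5]
        raise ValueError(f"each stratum needs exactly one case; offending strata include {bad.tolist()}")
    case_pos = np.flatnonzero(ys)
    return order, starts, counts, case_pos


def clogit_loglik(beta: np.ndarray, X: np.ndarray, starts: np.ndarray, counts: np.ndarray, case_pos: np.ndarray):
    """Conditional log-likelihood with analytic gradient and Hessian.

    ``X`` must be sorted by stratum (see ``_stratum_layout``); ``starts``
    indexes each stratum's first row, ``case_pos`` the case rows.
    """
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    em = np.exp(eta - np.repeat(m, counts))
    S = np.add.reduceat(em, starts)
    ll = float(np.sum(eta[case_pos]) - np.sum(m + np.log(S)))
    w = em / np.repeat(S, counts)
    xbar = np.add.reduceat(X * w[:, None], starts, axis=0)
    grad = X[case_pos].sum(axis=0) - xbar.sum(axis=0)
    Xc = X - np.repeat(xbar, counts, axis=0)
    H = -(Xc * w[:, None]).T @ Xc
    return ll, grad, H


class ConditionalLogitSSF(BaseEstimator):
    """Conditional logistic regression over matched case-control strata.

    Parameters
    ----------
    max_iter : Newton iteration cap.
    tol_grad : convergence when max |gradient| falls below this.
    tol_ll : ... or when the relative log-likelihood change does.

    Attributes (after fit)
    ----------------------
    coef_, bse_, zvalues_, pvalues_ : per-column estimates and Wald inference.
    loglik_, loglik_null_, aic_ : fit quality; aic_ = -2 loglik_ + 2 p.
    n_strata_, n_iter_, converged_ : fitting diagnostics.  Non-convergence
    with monotonically growing coefficients indicates separation, which is
    reported (``separation_suspected_``), never silently penalized away.
    """

    def __init__(self, max_iter: int = 60, tol_grad: float = 1e-8, tol_ll: float = 1e-12):
        self.max_iter = max_iter
        self.tol_grad = tol_grad
        self.tol_ll = tol_ll

    def fit(self, X, y, groups=None):
        if groups is None:
            raise ValueError("groups (stratum ids) are required")
        X = check_array(X, dtype=float)
        y = np.asarray(y).astype(bool).ravel()
        groups = np.asarray(groups).ravel()
        if not (len(X) == len(y) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        order, starts, counts, case_pos = _stratum_layout(groups, y)
        Xs = X[order]
        n, p = Xs.shape
        if len(starts) < p + 1:
            raise ValueError(f"need at least {p + 1} strata to fit {p} terms")

        beta = np.zeros(p)
        ll, grad, H = clogit_loglik(beta, Xs, starts, counts, case_pos)
        self.loglik_null_ = ll if not np.any(beta) else None
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(-H, grad)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular Hessian: collinear terms among columns {self._collinear_cols(H)}"
                ) from err
            # step-halving line search on the conditional likelihood
            scale = 1.0
            for _ in range(40):
                ll_new, grad_new, H_new = clogit_loglik(beta + scale * step, Xs, starts, counts, case_pos)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
            ll, grad, H = ll_new, grad_new, H_new
            if np.max(np.abs(grad)) < self.tol_grad or rel < self.tol_ll:
                converged = True
                break

        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.coef_ = beta
        self.loglik_ = ll
        self.aic_ = -2.0 * ll + 2.0 * p
        self.n_strata_ = len(starts)
        self.separation_suspected_ = bool(not converged and np.max(np.abs(beta)) > 10.0)
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
        self.cov_params_ = cov
        self.bse_ = se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = beta / se
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        return self

    @staticmethod
    def _collinear_cols(H: np.ndarray) -> list[int]:
        vals, vecs = np.linalg.eigh(-H)
        null = np.abs(vals) < 1e-10 * max(1.0, np.abs(vals).max())
        cols = np.unique(np.argsort(-np.abs(vecs[:, null]), axis=0)[:2].ravel()) if null.any() else []
        return list(map(int, cols))

    def decision_function(self, X):
        return check_array(X, dtype=float) @ self.coef_

    def loglik_at(self, beta, X, y, groups):
        """Conditional log-likelihood of arbitrary coefficients on a dataset."""
        order, starts, counts, case_pos = _stratum_layout(
            np.asarray(groups).ravel(), np.asarray(y).astype(bool).ravel()
        )
        ll, _, _ = clogit_loglik(np.asarray(beta, float), np.asarray(X, float)[order], starts, counts, case_pos)
        return ll


@dataclass
class ClogitFit:
    """One fitted conditional-logit model on named terms."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float
    n_strata: int
    converged: bool
    iterations: int
    separation_suspected: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(term=self.terms, beta=self.beta, se=self.se, z=self.z, p=self.p)
        )

    def to_dict(self) -> dict:
        return dict(
            terms=list(self.terms),
            beta=[float(b) for b in self.beta],
            se=[float(s) for s in self.se],
            z=[float(z) for z in self.z],
            p=[float(p) for p in self.p],
            loglik=float(self.loglik),
            aic=float(self.aic),
            n_strata=int(self.n_strata),
            converged=bool(self.converged),
            iterations=int(self.iterations),
        )


def build_design(steps: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Design matrix for named terms; ``"a:b"`` is the product of columns a and b."""
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate terms in model specification")
    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            for f in (a, b):
                if f not in steps.columns:
                    raise ValueError(f"interaction factor {f!r} not a column")
            cols.append(steps[a].to_numpy(float) * steps[b].to_numpy(float))
        else:
            if t not in steps.columns:
                raise ValueError(f"term {t!r} not a column")
            cols.append(steps[t].to_numpy(float))
    return np.column_stack(cols)


def fit_clogit(steps: pd.DataFrame, terms: list[str], **est_kwargs) -> ClogitFit:
    """Fit a conditional-logit model on a step table (needs stratum_id, is_case)."""
    X = build_design(steps, terms)
    est = ConditionalLogitSSF(**est_kwargs).fit(
        X, steps["is_case"].to_numpy(bool), groups=steps["stratum_id"].to_numpy()
    )
    return ClogitFit(
        terms=list(terms),
        beta=est.coef_,
        se=est.bse_,
        z=est.zvalues_,
        p=est.pvalues_,
        loglik=est.loglik_,
        aic=est.aic_,
        n_strata=est.n_strata_,
        converged=est.converged_,
        iterations=est.n_iter_,
        separation_suspected=est.separation_suspected_,
    )


def _droppable(terms: list[str]) -> list[str]:
    """Terms removable while respecting marginality (main effects stay while a product uses them)."""
    in_products = set()
    for t in terms:
        if ":" in t:
            in_products.update(t.split(":", 1))
    return [t for t in terms if ":" in t or t not in in_products]


@dataclass
class SelectionTrace:
    """The backward-elimination record: every fitted model, plus the best."""

    fits: list[ClogitFit]
    dropped: list[str | None]
    best: ClogitFit = field(init=False)

    def __post_init__(self) -> None:
        best_aic = min(f.aic for f in self.fits)
        candidates = [f for f in self.fits if abs(f.aic - best_aic) < 1e-9]
        self.best = min(candidates, key=lambda f: len(f.terms))

    def table(self) -> pd.DataFrame:
        all_terms: list[str] = []
        for f in self.fits:
            for t in f.terms:
                if t not in all_terms:
                    all_terms.append(t)
        rows = []
        for i, (f, d) in enumerate(zip(self.fits, self.dropped), start=1):
            row = {"model": i, "dropped": d, "aic": f.aic, "loglik": f.loglik}
            coefs = dict(zip(f.terms, f.beta))
            for t in all_terms:
                row[t] = coefs.get(t, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def backward_select(steps: pd.DataFrame, full_terms: list[str], alpha: float = 0.05) -> SelectionTrace:
    """Backward stepwise elimination by Wald significance, scored by AIC.

    At each stage the single droppable term with the largest Wald p among
    those with p > alpha is removed (a main effect is never dropped while
    an interaction containing it remains).  Every fitted model is
    recorded; the best model is the lowest-AIC fit, ties broken toward
    fewer terms.
    """
    terms = list(full_terms)
    fits = [fit_clogit(steps, terms)]
    dropped: list[str | None] = [None]
    while len(terms) > 1:
        fit = fits[-1]
        pmap = dict(zip(fit.terms, fit.p))
        candidates = [(pmap[t], t) for t in _droppable(fit.terms) if pmap[t] > alpha]
        if not candidates:
            break
        _, worst = max(candidates)
        terms = [t for t in terms if t != worst]
        fits.append(fit_clogit(steps, terms))
        dropped.append(worst)
    return SelectionTrace(fits=fits, dropped=dropped)
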