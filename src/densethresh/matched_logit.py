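"""Conditional logistic regression for 1:m matched case-control sets.

Each matched set contributes one case and ``m`` controls sharing the
matching strata.  Conditioning on "exactly one case per set" removes the
per-set nuisance intercepts and leaves a softmax likelihood: the set
contribution is ``exp(x_case·β) / Σ_{j in set} exp(x_j·β)``.  The model is
fitted by Newton–Raphson with an analytic gradient and Hessian, and models
are compared with the Akaike information criterion AIC = 2k − 2ℓ̂ and
likelihood-ratio tests.

Effect sizes are reported as *standardized* odds ratios — the change in
odds for a one-standard-deviation increase in the predictor — so that
measures on different scales are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "AnalysisDataset",
    "ClogitFit",
    "conditional_loglik",
    "fit_clogit",
    "lr_test",
    "standardized_or",
    "fit_interaction",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

MAX_ITER = 50
SCORE_TOL = 1e-8
LOGLIK_RTOL = 1e-12


class SeparationError(RuntimeError):
    """Perfect separation: the conditional likelihood has no finite maximum."""


@dataclass
class AnalysisDataset:
    """Matched-set design matrix for conditional logistic regression.

    Parameters
    ----------
    x:
        (n_subjects, k) predictor matrix, subjects grouped so that members
        of a set are contiguous (any input order is accepted; rows are
        sorted by ``set_id`` on construction).
    set_id:
        Integer set label per subject.
    is_case:
        Boolean per subject; exactly one True per set.
    columns:
        Predictor names, length k.
    """

    x: np.ndarray
    set_id: np.ndarray
    is_case: np.ndarray
    columns: tuple = ()
    # derived, populated in __post_init__
    set_start: np.ndarray = field(init=False, repr=False)
    case_rows: np.ndarray = field(init=False, repr=False)
    sds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.shape[0] == 1 and np.asarray(self.set_id).size != 1:
            x = x.T
        set_id = np.asarray(self.set_id)
        is_case = np.asarray(self.is_case, dtype=bool)
        if not (x.shape[0] == set_id.size == is_case.size):
            raise ValueError("x, set_id and is_case must agree in length")
        order = np.argsort(set_id, kind="stable")
        x, set_id, is_case = x[order], set_id[order], is_case[order]
        starts = np.flatnonzero(np.r_[True, set_id[1:] != set_id[:-1]])
        counts = np.diff(np.r_[starts, set_id.size])
        cases_per_set = np.add.reduceat(is_case.astype(int), starts)
        if np.any(cases_per_set != 1):
            bad = set_id[starts[np.flatnonzero(cases_per_set != 1)[0]]]
            raise ValueError(f"set {bad!r} does not have exactly one case")
        if np.any(counts < 2):
            bad = set_id[starts[np.flatnonzero(counts < 2)[0]]]
            raise ValueError(f"set {bad!r} has no controls")
        if not self.columns:
            self.columns = tuple(f"x{j}" for j in range(x.shape[1]))
        if len(self.columns) != x.shape[1]:
            raise ValueError("columns length must match predictor count")
        self.x, self.set_id, self.is_case = x, set_id, is_case
        self.set_start = starts
        self.case_rows = np.flatnonzero(is_case)
        self.sds = x.std(axis=0, ddof=1)

    @property
    def n_sets(self) -> int:
        return self.set_start.size

    @property
    def k(self) -> int:
        return self.x.shape[1]

    def subset_columns(self, names: Sequence[str]) -> "AnalysisDataset":
        idx = [self.columns.index(n) for n in names]
        return AnalysisDataset(
            x=self.x[:, idx],
            set_id=self.set_id,
            is_case=self.is_case,
            columns=tuple(names),
        )


@dataclass
class ClogitFit:
    """A fitted conditional logistic regression."""

    beta: np.ndarray  # per raw predictor unit
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    n_sets: int
    columns: tuple
    sds: np.ndarray
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return self.beta.size

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def chisq(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def standardized_or(self) -> dict:
        return standardized_or(self, self.sds)

    def linear_predictor(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.beta

    def to_dict(self) -> dict:
        ors = self.standardized_or()
        return {
            "columns": list(self.columns),
            "beta": self.beta.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "aic": self.aic,
            "chisq": self.chisq,
            "n_sets": self.n_sets,
            "converged": self.converged,
            "standardized_or": {
                name: {"or": o, "ci_low": lo, "ci_high": hi}
                for name, (o, lo, hi) in ors.items()
            },
            "settings": {
                "max_iter": MAX_ITER,
                "score_tol": SCORE_TOL,
                "loglik_rtol": LOGLIK_RTOL,
                "sd_convention": "pooled cases+controls, ddof=1",
            },
        }


def _set_softmax(dataset: AnalysisDataset, beta: np.ndarray):
    """Per-subject softmax weights within sets and per-set log-normalizers."""
    eta = dataset.x @ beta
    starts = dataset.set_start
    mx = np.maximum.reduceat(eta, starts)
    mx_per = np.repeat(mx, np.diff(np.r_[starts, eta.size]))
    ex = np.exp(eta - mx_per)
    denom = np.add.reduceat(ex, starts)
    logz = mx + np.log(denom)
    p = ex / np.repeat(denom, np.diff(np.r_[starts, eta.size]))
    return eta, p, logz


def conditional_loglik(beta: np.ndarray, dataset: AnalysisDataset) -> float:
    """Conditional log-likelihood Σ_s [x_case·β − log Σ_j exp(x_j·β)].

    Guarded by within-set max subtraction, so it stays finite for linear
    predictors up to ~±700.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta, _, logz = _set_softmax(dataset, beta)
    return float(eta[dataset.case_rows].sum() - logz.sum())


def _score_info(dataset: AnalysisDataset, beta: np.ndarray):
    """Log-likelihood, score vector, and observed information matrix."""
    eta, p, logz = _set_softmax(dataset, beta)
    ll = float(eta[dataset.case_rows].sum() - logz.sum())
    starts = dataset.set_start
    x = dataset.x
    px = p[:, None] * x
    mean_x = np.add.reduceat(px, starts, axis=0)  # (n_sets, k)
    score = x[dataset.case_rows].sum(axis=0) - mean_x.sum(axis=0)
    # E[x xᵀ] within sets minus outer(mean)
    exx = np.add.reduceat(px[:, :, None] * x[:, None, :], starts, axis=0)
    info = exx.sum(axis=0) - np.einsum("si,sj->ij", mean_x, mean_x)
    return ll, score, info


def fit_clogit(dataset: AnalysisDataset, max_iter: int = MAX_ITER) -> ClogitFit:
    """Newton–Raphson fit with step-halving fallback.

    Convergence when the max absolute score < 1e-8 or the relative
    log-likelihood change < 1e-12.  Diverging coefficients (perfect
    separation) and singular information raise, naming the column.
    """
    k = dataset.k
    beta = np.zeros(k)
    ll_null = conditional_loglik(beta, dataset)
    ll, score, info = ll_null, None, None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, score, info = _score_info(dataset, beta)
        # the conditional likelihood's supremum under separation is 0
        # (every case probability -> 1); a finite MLE keeps ll bounded away
        if ll > -1e-6 * dataset.n_sets or np.max(np.abs(beta * dataset.sds)) > 50.0:
            worst = dataset.columns[int(np.argmax(np.abs(beta * dataset.sds)))]
            raise SeparationError(
                f"coefficient for {worst!r} diverging; perfect separation?"
            )
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            worst = dataset.columns[int(np.argmax(np.diag(info) == np.min(np.diag(info))))]
            raise np.linalg.LinAlgError(
                f"singular information matrix (near-constant column {worst!r}?)"
            ) from exc
        # step-halving: accept the first step that does not decrease loglik
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, dataset)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(ll_new - ll) <= LOGLIK_RTOL * max(1.0, abs(ll)):
            ll = ll_new
            converged = True
            break
    ll, score, info = _score_info(dataset, beta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular information at the optimum") from exc
    return ClogitFit(
        beta=beta,
        covariance=cov,
        loglik=ll,
        loglik_null=ll_null,
        n_sets=dataset.n_sets,
        columns=dataset.columns,
        sds=dataset.sds.copy(),
        converged=converged,
        n_iter=n_iter,
    )


def aic(fit: ClogitFit) -> float:
    """AIC = 2k − 2·maximized log-likelihood."""
    return fit.aic


def lr_test(full: ClogitFit, nested: ClogitFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested model against a fuller one.

    Returns ``(statistic, df, p)`` with the statistic clipped at 0 (up to a
    1e-8 numerical tolerance) and an upper-tail chi-square p-value.
    """
    if not set(nested.columns) <= set(full.columns):
        raise ValueError(
            f"models are not nested: {nested.columns} is not a subset of {full.columns}"
        )
    if full.n_sets != nested.n_sets:
        raise ValueError("models were fitted on different numbers of sets")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-8:
        raise ValueError(f"negative LR statistic {stat}: models not nested on these data?")
    stat = max(stat, 0.0)
    df = full.k - nested.k
    p = 1.0 if df == 0 and stat == 0.0 else float(chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat <= 1e-8 else 0.0
    return stat, df, p


def standardized_or(fit: ClogitFit, sds: np.ndarray) -> dict:
    """Per-column standardized odds ratios with Wald 95% CIs.

    ``OR_j = exp(beta_j · sd_j)``; the CI is ``exp((beta_j ± 1.96·se_j)·sd_j)``.
    """
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    if np.any(sds <= 0):
        raise ValueError("standardized ORs require positive SDs")
    se = fit.se
    out = {}
    for j, name in enumerate(fit.columns):
        out[name] = (
            float(np.exp(fit.beta[j] * sds[j])),
            float(np.exp((fit.beta[j] - _Z95 * se[j]) * sds[j])),
            float(np.exp((fit.beta[j] + _Z95 * se[j]) * sds[j])),
        )
    return out


def fit_interaction(
    dataset: AnalysisDataset,
    predictor: str,
    group_indicator: np.ndarray,
) -> dict:
    """Predictor × group interaction fit with per-group odds ratios.

    ``group_indicator`` is 0/1 per subject (1 = the second group, e.g.
    interval cancer) and must be constant within each matched set — a set is
    one woman's case plus her matched controls, and the mode is the case's.

    The model has columns ``(predictor, predictor × indicator)`` so the
    group-0 log-OR is β₁ and the group-1 log-OR is β₁ + β₂; SEs come from
    the covariance.  A likelihood-ratio test against the no-interaction
    model tests whether the association differs between groups.
    """
    g = np.asarray(group_indicator, dtype=float)
    if g.size != dataset.x.shape[0]:
        raise ValueError("group_indicator must have one entry per subject")
    if not np.all(np.isin(g, (0.0, 1.0))):
        raise ValueError("group_indicator must be 0/1")
    # g must be aligned with dataset.set_id / dataset.x row order
    xcol = dataset.x[:, dataset.columns.index(predictor)]
    starts = dataset.set_start
    counts = np.diff(np.r_[starts, g.size])
    first = g[starts]
    if np.any(np.abs(g - np.repeat(first, counts)) > 0):
        bad = dataset.set_id[starts[np.flatnonzero(
            np.add.reduceat(np.abs(g - np.repeat(first, counts)), starts) > 0)[0]]]
        raise ValueError(f"group indicator varies within set {bad!r}")
    inter = AnalysisDataset(
        x=np.column_stack([xcol, xcol * g]),
        set_id=dataset.set_id,
        is_case=dataset.is_case,
        columns=(predictor, f"{predictor}:group"),
    )
    base = AnalysisDataset(
        x=xcol[:, None],
        set_id=dataset.set_id,
        is_case=dataset.is_case,
        columns=(predictor,),
    )
    fit_full = fit_clogit(inter)
    fit_base = fit_clogit(base)
    stat, df, p = lr_test(fit_full, fit_base)
    sd = float(np.std(xcol, ddof=1))
    b1, b2 = fit_full.beta
    cov = fit_full.covariance
    se_g0 = float(np.sqrt(cov[0, 0]))
    se_g1 = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))
    per_group = {}
    for label, logor, se in (("group0", b1, se_g0), ("group1", b1 + b2, se_g1)):
        per_group[label] = {
            "or": float(np.exp(logor * sd)),
            "ci_low": float(np.exp((logor - _Z95 * se) * sd)),
            "ci_high": float(np.exp((logor + _Z95 * se) * sd)),
        }
    return {
        "fit": fit_full,
        "fit_no_interaction": fit_base,
        "per_group_or": per_group,
        "lr_stat": stat,
        "lr_df": df,
        "lr_p": p,
        "sd": sd,
    }
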