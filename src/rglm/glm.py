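"""Generalized linear model core: fitting, AIC, univariate screening scores,
and forward stepwise selection.

Two families are supported, matching the outcome types the ensemble predicts:

* ``gaussian`` — identity link, ordinary least squares. The log-likelihood uses
  the profile maximum-likelihood estimate of the error variance,
  ``loglik = -n/2 * (log(2*pi*RSS/n) + 1)``, so AIC values are comparable
  across fits with equal ``n`` and the parameter count ``k`` is the number of
  regression coefficients (intercept included, variance not counted).
* ``binomial`` — logit link, Bernoulli likelihood, fitted by safeguarded
  Newton-Raphson (step-halving on likelihood decrease, 25-iteration cap).

Forward selection starts from the intercept-only model and at every step adds
the candidate whose inclusion lowers AIC the most, stopping when no candidate
strictly lowers it.  Candidates whose augmented fit fails (non-finite or
diverging coefficients, singular information) are treated as AIC = +inf for
that step.  Ties are broken by candidate list order.

The module-level ``fit_glm`` / ``forward_select`` operate on a single design;
the ``_batch_*`` helpers fit many small GLMs simultaneously (one per candidate
term) and are the computational workhorse of the ensemble builder.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Family",
    "FitResult",
    "SelectedModel",
    "aic",
    "fit_glm",
    "univariate_association",
    "forward_select",
]

_MAX_NEWTON_ITER = 25
_COEF_DIVERGENCE = 1e6  # |beta| beyond this is treated as a failed fit
_PROB_CLIP = 1e-10
_LOG_2PI = math.log(2.0 * math.pi)


class Family(enum.Enum):
    """Outcome family of a GLM (link is implied: identity / logit)."""

    GAUSSIAN = "gaussian"
    BINOMIAL = "binomial"

    @property
    def link(self) -> str:
        return "identity" if self is Family.GAUSSIAN else "logit"

    @classmethod
    def from_name(cls, name: "str | Family") -> "Family":
        if isinstance(name, Family):
            return name
        try:
            return cls(str(name).lower())
        except ValueError:
            raise ValueError(
                f"unknown family {name!r}; supported: gaussian, binomial"
            ) from None


@dataclass
class FitResult:
    """Maximum-likelihood fit of one GLM.

    ``coefficients`` maps a term key to its coefficient; the intercept is
    stored under the key ``"intercept"``.  ``k`` counts all estimated
    regression coefficients including the intercept, and the identity
    ``aic == -2 * loglik + 2 * k`` holds by construction.
    """

    coefficients: dict
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    k: int
    dropped: tuple = ()  # aliased columns removed from a rank-deficient design

    @property
    def coef_vector(self) -> np.ndarray:
        return np.asarray(list(self.coefficients.values()), dtype=float)


@dataclass
class SelectedModel:
    """Result of forward stepwise selection.

    ``selected_terms`` is in selection order; ``aic_path`` records the model
    AIC after each accepted step (index 0 = intercept-only model).
    """

    selected_terms: list
    fit: FitResult
    candidate_terms: list
    aic_path: list = field(default_factory=list)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, ``-2*loglik + 2*k``, with ``k >= 1``."""
    if k < 1:
        raise ValueError("k must be >= 1 (the intercept is always estimated)")
    return -2.0 * float(loglik) + 2.0 * int(k)


def _gaussian_loglik(rss: float, n: int) -> float:
    # Profile MLE of sigma^2 = RSS/n; degenerate exact fits get sigma^2 -> 0,
    # which we floor to keep the likelihood finite (AIC comparisons among
    # exact fits are then decided by k alone).
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (_LOG_2PI + math.log(sigma2) + 1.0)


def _bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _drop_aliased(design: np.ndarray) -> "tuple[np.ndarray, list[int]]":
    """Greedily keep columns left-to-right while they increase rank.

    Later-entered aliased columns are dropped, so the result is deterministic
    given column order.  Cheap for the small designs the ensemble produces.
    """
    n, p = design.shape
    if np.linalg.matrix_rank(design) == p:
        return design, []
    keep: list[int] = []
    rank = 0
    for j in range(p):
        cols = keep + [j]
        r = np.linalg.matrix_rank(design[:, cols])
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [j for j in range(p) if j not in keep]
    return design[:, keep], dropped


def _newton_logistic(
    design: np.ndarray,
    y: np.ndarray,
    start: "np.ndarray | None" = None,
) -> "tuple[np.ndarray, float, bool, bool]":
    """Safeguarded Newton-Raphson for a Bernoulli GLM with logit link.

    Returns ``(beta, loglik, converged, ok)``; ``ok`` is False on a genuinely
    failed fit (singular information or diverging coefficients).
    """
    n, p = design.shape
    beta = np.zeros(p) if start is None else start.astype(float).copy()
    eta = design @ beta
    prob = expit(eta)
    ll = float(eta @ y - np.logaddexp(0.0, eta).sum())
    converged = False
    for _ in range(_MAX_NEWTON_ITER):
        w = prob * (1.0 - prob)
        # Fisher information X' W X; singular => separation or aliasing
        xtw = design.T * w
        info = xtw @ design
        score = design.T @ (y - prob)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, ll, False, False
        if not np.all(np.isfinite(step)):
            return beta, ll, False, False
        # step-halving: accept the first step that does not lower the loglik
        scale = 1.0
        for _half in range(20):
            cand = beta + scale * step
            eta = design @ cand
            prob_new = expit(eta)
            ll_new = float(eta @ y - np.logaddexp(0.0, eta).sum())
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = float(np.max(np.abs(cand - beta)))
        ll_rel = (ll_new - ll) / (abs(ll_new) + 0.1)
        beta, prob, ll = cand, prob_new, ll_new
        if np.max(np.abs(beta)) > _COEF_DIVERGENCE:
            return beta, ll, False, False
        if delta < 1e-8 or abs(ll_rel) < 1e-8:
            converged = True
            break
    if not np.all(np.isfinite(beta)):
        return beta, ll, False, False
    return beta, ll, converged, True


def fit_glm(
    family: "Family | str",
    design: np.ndarray,
    response: np.ndarray,
    term_names: "Sequence[Hashable] | None" = None,
) -> FitResult:
    """Fit one GLM by maximum likelihood.

    ``design`` must already contain the intercept column (conventionally the
    first).  Rank-deficient designs are handled by dropping later-entered
    aliased columns; the dropped column indices are reported on the result.
    """
    family = Family.from_name(family)
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.ndim != 2:
        raise ValueError("design must be a 2-d array")
    n, p = design.shape
    if n == 0:
        raise ValueError("design has zero rows")
    if n != response.shape[0]:
        raise ValueError("design rows and response length differ")
    if not (np.all(np.isfinite(design)) and np.all(np.isfinite(response))):
        raise ValueError("design/response contain non-finite values")

    names = list(term_names) if term_names is not None else [
        "intercept" if j == 0 else f"x{j}" for j in range(p)
    ]
    if len(names) != p:
        raise ValueError("term_names length must match design columns")

    work, dropped = _drop_aliased(design)
    kept = [j for j in range(p) if j not in dropped]
    k = work.shape[1]

    if family is Family.GAUSSIAN:
        beta, _, _, _ = np.linalg.lstsq(work, response, rcond=None)
        rss = float(np.sum((response - work @ beta) ** 2))
        ll = _gaussian_loglik(rss, n)
        converged = True
    else:
        if not np.all(np.isin(response, (0.0, 1.0))):
            raise ValueError("binomial response must be coded 0/1")
        beta, ll, converged, ok = _newton_logistic(work, response)
        if not ok and k == 1:
            # intercept-only fallback: logit of clipped sample prevalence
            prev = float(np.clip(response.mean(), 1e-6, 1.0 - 1e-6))
            beta = np.array([math.log(prev / (1.0 - prev))])
            ll = _bernoulli_loglik(np.full(n, prev), response)
            converged = False
        elif not ok:
            converged = False

    coefficients = {names[j]: float(b) for j, b in zip(kept, beta)}
    return FitResult(
        coefficients=coefficients,
        loglik=float(ll),
        aic=aic(ll, k),
        converged=bool(converged),
        n_obs=n,
        k=k,
        dropped=tuple(names[j] for j in dropped),
    )


# ---------------------------------------------------------------------------
# batched fitting (one small GLM per candidate, shared response)
# ---------------------------------------------------------------------------

def _batch_logistic(
    designs: np.ndarray,
    y: np.ndarray,
    start: "np.ndarray | None" = None,
) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
    """Fit C logistic models at once; ``designs`` has shape (C, n, p).

    Returns ``(beta (C,p), loglik (C,), ok (C,))``.  All models share the
    response and run the same safeguarded Newton updates in lock-step; models
    that fail (singular information, divergence) are masked out.  The
    log-likelihood is evaluated on the linear-predictor scale,
    ``y.eta - sum(log(1 + exp(eta)))``, which is exact even under separation.
    """
    C, n, p = designs.shape
    beta = np.zeros((C, p)) if start is None else start.astype(float).copy()
    ok = np.ones(C, dtype=bool)
    eta = np.matmul(designs, beta[:, :, None])[:, :, 0]
    prob = expit(eta)
    ll = eta @ y - np.logaddexp(0.0, eta).sum(axis=1)
    active = np.ones(C, dtype=bool)
    jitter = 1e-12 * np.eye(p)
    # re-subset the working batch lazily (copies are expensive): only when the
    # active fraction within it has dropped below a half
    idx = np.arange(C)
    D = designs
    for _ in range(_MAX_NEWTON_ITER):
        n_active = int(active.sum())
        if n_active == 0:
            break
        if n_active * 2 < len(idx):
            idx = np.flatnonzero(active)
            D = designs[idx]
        w = prob[idx] * (1.0 - prob[idx])
        Dt = D.transpose(0, 2, 1)
        info = np.matmul(Dt, D * w[:, :, None])
        score = np.matmul(Dt, (y[None, :] - prob[idx])[:, :, None])[:, :, 0]
        # tiny jitter keeps np.linalg.solve from raising on a few singular
        # members; genuinely singular fits are caught by the finiteness and
        # divergence checks below
        info += jitter
        try:
            step = np.linalg.solve(info, score[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("cpq,cq->cp", np.linalg.pinv(info), score)
        bad = ~np.all(np.isfinite(step), axis=1)
        scale = np.ones(len(idx))
        cand = beta[idx] + step
        for _half in range(20):
            eta_new = np.matmul(D, cand[:, :, None])[:, :, 0]
            pn = expit(eta_new)
            ll_new = eta_new @ y - np.logaddexp(0.0, eta_new).sum(axis=1)
            worse = ll_new < ll[idx] - 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
            cand[worse] = beta[idx][worse] + scale[worse, None] * step[worse]
        delta = np.max(np.abs(cand - beta[idx]), axis=1)
        # converged when coefficients settle or the deviance stops moving
        # (the latter catches separated fits whose coefficients drift outward)
        ll_rel = (ll_new - ll[idx]) / (np.abs(ll_new) + 0.1)
        beta[idx] = cand
        prob[idx] = pn
        ll[idx] = ll_new
        diverged = np.max(np.abs(cand), axis=1) > _COEF_DIVERGENCE
        bad |= diverged
        ok[idx[bad]] = False
        done = (delta < 1e-8) | (np.abs(ll_rel) < 1e-8) | bad
        active[idx[done]] = False
    ok &= np.all(np.isfinite(beta), axis=1) & np.isfinite(ll)
    return beta, ll, ok


def univariate_association(
    family: "Family | str",
    covariate: np.ndarray,
    response: np.ndarray,
) -> float:
    """Association score of one covariate with the outcome.

    Gaussian family: absolute Pearson correlation.  Binomial family: absolute
    Wald z statistic of the slope in a univariate logistic regression.
    Degenerate covariates (zero variance) and failed fits score 0, i.e. rank
    last in candidate screening.
    """
    scores = batch_univariate_association(
        family, np.asarray(covariate, dtype=float)[:, None], response
    )
    return float(scores[0])


def batch_univariate_association(
    family: "Family | str",
    covariates: np.ndarray,
    response: np.ndarray,
) -> np.ndarray:
    """Vectorized ``univariate_association`` over the columns of ``covariates``."""
    family = Family.from_name(family)
    X = np.asarray(covariates, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate and response lengths differ")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    n, T = X.shape
    sd = X.std(axis=0)
    nondeg = sd > 0
    scores = np.zeros(T)
    if not nondeg.any():
        return scores
    if family is Family.GAUSSIAN:
        ysd = y.std()
        if ysd == 0:
            return scores
        xc = X[:, nondeg] - X[:, nondeg].mean(axis=0)
        yc = y - y.mean()
        r = (xc * yc[:, None]).sum(axis=0) / (n * sd[nondeg] * ysd)
        scores[nondeg] = np.abs(np.clip(r, -1.0, 1.0))
        return scores
    # binomial: batched univariate logistic fits, design [1, x]
    idx = np.flatnonzero(nondeg)
    designs = np.empty((len(idx), n, 2))
    designs[:, :, 0] = 1.0
    designs[:, :, 1] = X[:, idx].T
    beta, _, ok = _batch_logistic(designs, y)
    # Wald z = beta1 / se(beta1), se from the inverse Fisher information
    eta = np.matmul(designs, beta[:, :, None])[:, :, 0]
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = prob * (1.0 - prob)
    info = np.matmul(designs.transpose(0, 2, 1), designs * w[:, :, None])
    det = info[:, 0, 0] * info[:, 1, 1] - info[:, 0, 1] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = info[:, 0, 0] / det
        z = np.abs(beta[:, 1]) / np.sqrt(var1)
    z[~ok | ~np.isfinite(z) | (det <= 0)] = 0.0
    scores[idx] = z
    return scores


def forward_select(
    family: "Family | str",
    terms: Sequence[Hashable],
    covariates: np.ndarray,
    response: np.ndarray,
) -> SelectedModel:
    """Forward stepwise selection by AIC over the given candidate covariates.

    ``covariates`` holds one column per entry of ``terms`` (deduplicated by
    the caller).  Starts from the intercept-only model; at each step the
    candidate with the largest AIC decrease is added; stops when no candidate
    strictly decreases AIC.  An empty candidate list yields the intercept-only
    model.
    """
    family = Family.from_name(family)
    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    terms = list(terms)
    if X.ndim != 2 or X.shape[1] != len(terms):
        raise ValueError("covariates must have one column per term")
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariate and response lengths differ")
    n = y.shape[0]

    if family is Family.GAUSSIAN:
        return _forward_gaussian(terms, X, y)
    return _forward_binomial(terms, X, y)


def _forward_gaussian(terms, X, y) -> SelectedModel:
    """Gaussian forward path via precomputed Gram matrices (n drops out)."""
    n, T = X.shape
    Z = np.column_stack([np.ones(n), X])  # col 0 = intercept
    G = Z.T @ Z
    gy = Z.T @ y
    yy = float(y @ y)

    selected: list[int] = []  # column indices into Z (1-based terms)
    cur_cols = [0]
    rss0 = yy - gy[0] ** 2 / n
    cur_ll = _gaussian_loglik(max(rss0, 0.0), n)
    cur_aic = aic(cur_ll, 1)
    aic_path = [cur_aic]
    remaining = list(range(1, T + 1))

    while remaining:
        best_aic = math.inf
        best_j = -1
        k_new = len(cur_cols) + 1
        for j in remaining:
            cols = cur_cols + [j]
            A = G[np.ix_(cols, cols)]
            b = gy[cols]
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(beta)):
                continue
            rss = yy - float(b @ beta)
            if rss < -1e-8 * max(yy, 1.0):
                continue
            cand_aic = aic(_gaussian_loglik(max(rss, 0.0), n), k_new)
            if cand_aic < best_aic - 1e-12:
                best_aic = cand_aic
                best_j = j
        if best_j < 0 or best_aic >= cur_aic:
            break
        cur_cols.append(best_j)
        selected.append(best_j)
        remaining.remove(best_j)
        cur_aic = best_aic
        aic_path.append(cur_aic)

    sel_terms = [terms[j - 1] for j in selected]
    design = Z[:, cur_cols]
    fit = fit_glm(
        Family.GAUSSIAN, design, y, term_names=["intercept"] + sel_terms
    )
    return SelectedModel(sel_terms, fit, list(terms), aic_path)


def _forward_binomial(terms, X, y) -> SelectedModel:
    n, T = X.shape
    ones = np.ones((n, 1))
    fit0 = fit_glm(Family.BINOMIAL, ones, y, term_names=["intercept"])
    cur_aic = fit0.aic
    cur_beta = fit0.coef_vector
    cur_design = ones
    selected: list[int] = []
    aic_path = [cur_aic]
    remaining = list(range(T))

    while remaining:
        k_cur = cur_design.shape[1]
        C = len(remaining)
        designs = np.empty((C, n, k_cur + 1))
        designs[:, :, :k_cur] = cur_design[None, :, :]
        designs[:, :, k_cur] = X[:, remaining].T
        warm = np.tile(np.append(cur_beta, 0.0), (C, 1))
        beta, ll, ok = _batch_logistic(designs, y, start=warm)
        aics = np.where(ok, -2.0 * ll + 2.0 * (k_cur + 1), math.inf)
        pos = int(np.argmin(aics))  # argmin is stable: first best wins ties
        if not math.isfinite(aics[pos]) or aics[pos] >= cur_aic:
            break
        j = remaining[pos]
        selected.append(j)
        remaining.remove(j)
        cur_design = np.column_stack([cur_design, X[:, j]])
        cur_beta = beta[pos]
        cur_aic = float(aics[pos])
        aic_path.append(cur_aic)

    sel_terms = [terms[j] for j in selected]
    if selected:
        fit = FitResult(
            coefficients={
                name: float(b)
                for name, b in zip(["intercept"] + sel_terms, cur_beta)
            },
            loglik=(cur_aic / -2.0) + (len(selected) + 1),
            aic=cur_aic,
            converged=True,
            n_obs=n,
            k=len(selected) + 1,
        )
    else:
        fit = fit0
    return SelectedModel(sel_terms, fit, list(terms), aic_path)
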