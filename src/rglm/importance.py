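"""Variable importance and a-posteriori ensemble thinning.

Three importance measures fall out of the ensemble construction:

* ``times_selected_by_forward_regression`` — in how many bags the term
  survived forward selection (the preferred measure; akin to the selection
  frequencies of stability selection);
* ``times_selected_as_candidates`` — in how many bags the term passed
  univariate screening;
* ``sum_abs_coef_by_forward_regression`` — the summed absolute GLM
  coefficients of the term across bags that selected it.

Thinning removes terms whose selection tally falls below a threshold and
refits each bag's GLM (no new selection round) on its surviving terms using
that bag's own rows.  A threshold above the number of bags strips every
covariate and the ensemble degenerates to the naive predictor, a constant.
The expected fraction of features surviving at relative threshold
``x = threshold / n_bags`` follows the empirical curve

    F(x) = exp(-e * (e*x) ** (0.775 * n_bags ** (0.0468 * (1 - ln x))))

with F(0) = 1, a monotonically decreasing function of x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensemble import BagModel, RGLMModel, Term, bag_response, term_covariates
from .glm import Family, fit_glm

__all__ = [
    "ImportanceRecord",
    "ThinnedModel",
    "importance",
    "thin",
    "predict_thinned",
    "expected_proportion_left",
    "observed_proportion_left",
    "CURVE_C1",
    "CURVE_C2",
]

CURVE_C1 = 0.775
CURVE_C2 = 0.0468


@dataclass
class ImportanceRecord:
    term: Term
    times_selected_by_forward_regression: int
    times_selected_as_candidates: int
    sum_abs_coef_by_forward_regression: float


@dataclass
class ThinnedModel:
    """A thinned ensemble: the base model plus per-bag refitted coefficients
    restricted to terms whose selection tally met the threshold."""

    base: RGLMModel
    threshold: int
    removed_terms: set
    bag_terms: "list[list]"          # surviving selected terms per bag
    bag_coefficients: "list[dict]"   # refitted {term|'intercept': coef} per bag


def importance(model: RGLMModel, level: str = "term") -> "list[ImportanceRecord]":
    """Tally the three importance measures across bags.

    ``level='term'`` reports each distinct term; ``level='feature'``
    aggregates over all terms containing each original feature (counting a
    term once per bag regardless of the feature's multiplicity in it).
    Records are sorted by selection tally, descending, stable on ties.
    """
    if level not in ("term", "feature"):
        raise ValueError("level must be 'term' or 'feature'")
    sel: dict = {}
    cand: dict = {}
    coef: dict = {}
    for bag in model.bags:
        for t in bag.candidate_terms:
            cand[t] = cand.get(t, 0) + 1
        for t in bag.model.selected_terms:
            sel[t] = sel.get(t, 0) + 1
            coef[t] = coef.get(t, 0.0) + abs(bag.model.fit.coefficients[t])
    keys = sorted(set(cand) | set(sel))
    if level == "feature":
        fsel: dict = {}
        fcand: dict = {}
        fcoef: dict = {}
        for t in keys:
            for f in sorted(set(t)):
                fsel[f] = fsel.get(f, 0) + sel.get(t, 0)
                fcand[f] = fcand.get(f, 0) + cand.get(t, 0)
                fcoef[f] = fcoef.get(f, 0.0) + coef.get(t, 0.0)
        records = [
            ImportanceRecord((f,), fsel[f], fcand[f], fcoef[f])
            for f in sorted(fsel)
        ]
    else:
        records = [
            ImportanceRecord(t, sel.get(t, 0), cand.get(t, 0), coef.get(t, 0.0))
            for t in keys
        ]
    records.sort(
        key=lambda r: -r.times_selected_by_forward_regression
    )
    return records


def thin(
    model: RGLMModel,
    threshold: int,
    X_train: np.ndarray,
    y_train: np.ndarray,
) -> ThinnedModel:
    """Remove terms selected in fewer than ``threshold`` bags and refit.

    Each bag keeps the subset of its originally selected terms that survive
    globally and is refit by a plain GLM (no renewed forward selection) on its
    own bootstrap rows.  Bags whose term set is unchanged keep their original
    coefficients, so a threshold of 0 reproduces the base model exactly.
    Bags left with no terms become intercept-only.
    """
    if not (0 <= threshold <= model.config.n_bags + 1):
        raise ValueError("threshold must lie in [0, n_bags + 1]")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    tallies = {
        r.term: r.times_selected_by_forward_regression
        for r in importance(model, level="term")
    }
    removed = {t for t, c in tallies.items() if c < threshold}
    fam = model.config.family
    bag_terms: list[list] = []
    bag_coefs: list[dict] = []
    for bag in model.bags:
        keep = [t for t in bag.model.selected_terms if t not in removed]
        bag_terms.append(keep)
        if len(keep) == len(bag.model.selected_terms):
            bag_coefs.append(dict(bag.model.fit.coefficients))
            continue
        rows = bag.bag_indices
        design = np.column_stack(
            [np.ones(len(rows))]
            + ([term_covariates(X_train[rows], keep)] if keep else [])
        )
        try:
            fit = fit_glm(fam, design, y_train[rows],
                          term_names=["intercept"] + keep)
            coefs = dict(fit.coefficients)
            for t in keep:  # aliased-and-dropped terms keep a zero coefficient
                coefs.setdefault(t, 0.0)
        except ValueError:
            coefs = {"intercept": _intercept_only(fam, y_train[rows])}
        if not all(math.isfinite(v) for v in coefs.values()):
            coefs = {"intercept": _intercept_only(fam, y_train[rows])}
            bag_terms[-1] = []
        bag_coefs.append(coefs)
    return ThinnedModel(model, int(threshold), removed, bag_terms, bag_coefs)


def _intercept_only(family: Family, y: np.ndarray) -> float:
    if family is Family.BINOMIAL:
        p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        return math.log(p / (1 - p))
    return float(y.mean())


def predict_thinned(
    thinned: ThinnedModel, X_new: np.ndarray, output: str = "response"
) -> np.ndarray:
    """Ensemble prediction of a thinned model (same aggregation as the base)."""
    X_new = np.asarray(X_new, dtype=float)
    model = thinned.base
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features:
        raise ValueError(f"X_new must have {model.n_features} features")
    fam = model.config.family
    agg = np.zeros(X_new.shape[0])
    for terms, coefs in zip(thinned.bag_terms, thinned.bag_coefficients):
        eta = np.full(X_new.shape[0], coefs["intercept"])
        if terms:
            beta = np.array([coefs[t] for t in terms])
            eta = eta + term_covariates(X_new, terms) @ beta
        if fam is Family.BINOMIAL:
            eta = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        agg += eta
    agg /= len(thinned.bag_terms)
    if output == "class":
        if fam is not Family.BINOMIAL:
            raise ValueError("'class' output requires a binomial model")
        return (agg >= model.config.classify_threshold).astype(int)
    return agg


def expected_proportion_left(x: float, n_bags: int) -> float:
    """Expected fraction of features surviving thinning at relative threshold
    ``x = threshold / n_bags``; the empirical curve F(x), clamped to [0, 1]."""
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must lie in [0, 1]")
    if n_bags < 1:
        raise ValueError("n_bags must be >= 1")
    if x == 0.0:
        return 1.0
    exponent = CURVE_C1 * n_bags ** (CURVE_C2 * (1.0 - math.log(x)))
    val = math.exp(-math.e * (math.e * x) ** exponent)
    return min(max(val, 0.0), 1.0)


def observed_proportion_left(model: RGLMModel, thinned: ThinnedModel) -> float:
    """Fraction of the distinct original features appearing in the base
    model's selected terms that survive in the thinned model; NaN when the
    base model selected nothing."""
    base_feats: set = set()
    for bag in model.bags:
        for t in bag.model.selected_terms:
            base_feats.update(t)
    if not base_feats:
        return float("nan")
    left: set = set()
    for terms in thinned.bag_terms:
        for t in terms:
            left.update(t)
    return len(left) / len(base_feats)
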