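"""Construction and application of the random GLM (RGLM) ensemble.

One *bag* is built from a bootstrap resample of the training observations and
a random subspace of the original features.  Interaction terms (products of
subspace features, up to ``max_interaction_order``) are generated, screened by
univariate association with the outcome on the bag rows, and the surviving
candidates enter forward stepwise selection by AIC.  The ensemble prediction
averages per-bag predictions: linear predictors for a continuous outcome,
predicted class-1 probabilities for a binary outcome (adjusted majority vote),
thresholded at ``classify_threshold`` for a hard class.

Out-of-bag (OOB) estimation aggregates, for every training sample, only the
bags whose bootstrap draw missed that sample, giving a nearly unbiased
accuracy estimate without a held-out set.

Reproducibility: a single master seed spawns one independent random substream
per bag, so the trained ensemble is bit-identical across runs regardless of
the order in which bags are built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations, combinations_with_replacement
from typing import Sequence

import numpy as np

from .defaults import resolve_n_features_in_bag
from .glm import (
    Family,
    SelectedModel,
    FitResult,
    batch_univariate_association,
    fit_glm,
    forward_select,
)

__all__ = [
    "Term",
    "EnsembleConfig",
    "BagModel",
    "RGLMModel",
    "draw_bag",
    "sample_subspace",
    "expand_interactions",
    "term_covariates",
    "screen_candidates",
    "fit_bag",
    "train_rglm",
    "predict",
    "oob_predict",
]

# A term is a sorted tuple of original-feature indices whose product forms a
# covariate.  Repeated indices are allowed (self-interactions, e.g. (3, 3) is
# the square of feature 3); plain features are 1-tuples.
Term = tuple


@dataclass
class EnsembleConfig:
    """Tuning parameters of the ensemble.

    ``n_features_in_bag="auto"`` resolves to the published default rule based
    on the effective feature count (see :mod:`rglm.defaults`).
    ``interaction_self_products`` controls whether powers of a feature
    (x_i^2, x_i^2 * x_j, ...) are generated alongside distinct-feature
    products; they are included by default because quadratic terms carry the
    class signal in variance-separated problems.
    """

    n_bags: int = 100
    n_features_in_bag: "int | str" = "auto"
    n_candidate_covariates: int = 50
    max_interaction_order: int = 1
    family: "Family | str" = Family.BINOMIAL
    classify_threshold: float = 0.5
    seed: int = 0
    interaction_self_products: bool = True

    def __post_init__(self):
        self.family = Family.from_name(self.family)
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if self.n_candidate_covariates < 1:
            raise ValueError("n_candidate_covariates must be >= 1")
        if self.max_interaction_order not in (1, 2, 3):
            raise ValueError("max_interaction_order must be 1, 2 or 3")
        if not (0.0 < self.classify_threshold < 1.0):
            raise ValueError("classify_threshold must lie in (0, 1)")
        if self.n_features_in_bag != "auto":
            if int(self.n_features_in_bag) < 1:
                raise ValueError("n_features_in_bag must be >= 1 or 'auto'")

    def resolved(self, n_features: int) -> "EnsembleConfig":
        """Return a copy with ``n_features_in_bag`` resolved to an integer."""
        if self.n_features_in_bag == "auto":
            m = resolve_n_features_in_bag(n_features, self.max_interaction_order)
        else:
            m = int(self.n_features_in_bag)
        if m > n_features:
            raise ValueError(
                f"n_features_in_bag={m} exceeds the {n_features} available features"
            )
        return replace(self, n_features_in_bag=m)


@dataclass
class BagModel:
    """Everything recorded for one bag."""

    bag_indices: np.ndarray          # bootstrap draw, length n (with repeats)
    oob_indices: np.ndarray          # samples absent from the draw
    subspace: np.ndarray             # original-feature indices, sorted
    candidate_terms: list            # terms surviving univariate screening
    model: SelectedModel             # forward-selected GLM on the bag rows


@dataclass
class RGLMModel:
    """A trained RGLM ensemble; sufficient for prediction, OOB estimation,
    variable importance and thinning."""

    config: EnsembleConfig
    bags: "list[BagModel]"
    n_samples: int
    n_features: int
    feature_names: "list[str]"
    y_summary: float                 # training prevalence (binomial) or mean

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        cfg = self.config
        doc = {
            "config": {
                "n_bags": cfg.n_bags,
                "n_features_in_bag": cfg.n_features_in_bag,
                "n_candidate_covariates": cfg.n_candidate_covariates,
                "max_interaction_order": cfg.max_interaction_order,
                "family": cfg.family.value,
                "classify_threshold": cfg.classify_threshold,
                "seed": cfg.seed,
                "interaction_self_products": cfg.interaction_self_products,
            },
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "feature_names": self.feature_names,
            "y_summary": self.y_summary,
            "bags": [
                {
                    "bag_indices": bag.bag_indices.tolist(),
                    "subspace": bag.subspace.tolist(),
                    "candidate_terms": [list(t) for t in bag.candidate_terms],
                    "selected_terms": [list(t) for t in bag.model.selected_terms],
                    "intercept": bag.model.fit.coefficients["intercept"],
                    "coefficients": [
                        bag.model.fit.coefficients[t]
                        for t in bag.model.selected_terms
                    ],
                    "aic": bag.model.fit.aic,
                    "loglik": bag.model.fit.loglik,
                }
                for bag in self.bags
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "RGLMModel":
        doc = json.loads(text)
        cfg = EnsembleConfig(**doc["config"])
        n = doc["n_samples"]
        bags = []
        for b in doc["bags"]:
            bag_idx = np.asarray(b["bag_indices"], dtype=np.int64)
            oob = np.setdiff1d(np.arange(n), bag_idx)
            selected = [tuple(t) for t in b["selected_terms"]]
            coefs = {"intercept": b["intercept"]}
            coefs.update({t: c for t, c in zip(selected, b["coefficients"])})
            fit = FitResult(
                coefficients=coefs,
                loglik=b["loglik"],
                aic=b["aic"],
                converged=True,
                n_obs=len(bag_idx),
                k=len(selected) + 1,
            )
            model = SelectedModel(
                selected_terms=selected,
                fit=fit,
                candidate_terms=[tuple(t) for t in b["candidate_terms"]],
            )
            bags.append(
                BagModel(
                    bag_indices=bag_idx,
                    oob_indices=oob,
                    subspace=np.asarray(b["subspace"], dtype=np.int64),
                    candidate_terms=model.candidate_terms,
                    model=model,
                )
            )
        return cls(
            config=cfg,
            bags=bags,
            n_samples=n,
            n_features=doc["n_features"],
            feature_names=list(doc["feature_names"]),
            y_summary=float(doc["y_summary"]),
        )


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

def draw_bag(n_samples: int, rng: np.random.Generator):
    """One bootstrap draw of size ``n_samples`` plus its OOB complement."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    bag = rng.integers(0, n_samples, size=n_samples)
    oob = np.setdiff1d(np.arange(n_samples), bag)
    return bag, oob


def sample_subspace(
    n_features: int, n_features_in_bag: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw without replacement of ``n_features_in_bag`` feature
    indices, returned sorted."""
    if not (1 <= n_features_in_bag <= n_features):
        raise ValueError("need 1 <= n_features_in_bag <= n_features")
    return np.sort(rng.choice(n_features, size=n_features_in_bag, replace=False))


def expand_interactions(
    subspace: Sequence[int], order: int, include_self: bool = True
) -> "list[Term]":
    """All product terms of subspace features of size 1..order.

    With ``include_self=True`` (the ensemble default) repeated indices are
    allowed, so powers such as x_i^2 appear; with ``include_self=False`` only
    products of distinct features are generated.  Terms are emitted in
    deterministic order: by size, then lexicographically.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    feats = sorted(int(f) for f in subspace)
    chooser = combinations_with_replacement if include_self else combinations
    terms: list[Term] = []
    for size in range(1, order + 1):
        terms.extend(chooser(feats, size))
    return terms


def term_covariates(X: np.ndarray, terms: "Sequence[Term]") -> np.ndarray:
    """Covariate matrix with one product column per term."""
    n = X.shape[0]
    out = np.empty((n, len(terms)))
    for j, t in enumerate(terms):
        col = X[:, t[0]].copy()
        for f in t[1:]:
            col *= X[:, f]
        out[:, j] = col
    return out


def screen_candidates(
    terms: "Sequence[Term]",
    covariates: np.ndarray,
    y_bag: np.ndarray,
    n_candidate_covariates: int,
    family: "Family | str",
) -> "list[Term]":
    """Rank terms by univariate association with the outcome on the bag rows
    and keep the top ``n_candidate_covariates``; ties break lexicographically."""
    terms = list(terms)
    if not terms:
        raise ValueError("terms must be nonempty")
    scores = batch_univariate_association(family, covariates, y_bag)
    order = sorted(range(len(terms)), key=lambda i: (-scores[i], terms[i]))
    keep = order[: min(n_candidate_covariates, len(terms))]
    return [terms[i] for i in keep]


# ---------------------------------------------------------------------------
# per-bag fitting and ensemble training
# ---------------------------------------------------------------------------

def fit_bag(
    X: np.ndarray, y: np.ndarray, config: EnsembleConfig, rng: np.random.Generator
) -> BagModel:
    """Build one bag: bootstrap draw, random subspace, interaction expansion,
    candidate screening, forward selection — all on the bag rows."""
    n, N = X.shape
    cfg = config if config.n_features_in_bag != "auto" else config.resolved(N)
    bag_idx, oob = draw_bag(n, rng)
    subspace = sample_subspace(N, int(cfg.n_features_in_bag), rng)
    terms = expand_interactions(
        subspace, cfg.max_interaction_order, cfg.interaction_self_products
    )
    X_bag = X[bag_idx]
    y_bag = y[bag_idx]

    if cfg.family is Family.BINOMIAL and len(np.unique(y_bag)) < 2:
        # single-class bootstrap draw: no information for selection; keep an
        # intercept-only model at the clipped bag prevalence
        fit = fit_glm(Family.BINOMIAL, np.ones((len(y_bag), 1)), y_bag,
                      term_names=["intercept"])
        model = SelectedModel([], fit, [], [fit.aic])
        return BagModel(bag_idx, oob, subspace, [], model)

    covs = term_covariates(X_bag, terms)
    candidates = screen_candidates(
        terms, covs, y_bag, cfg.n_candidate_covariates, cfg.family
    )
    pos = {t: j for j, t in enumerate(terms)}
    cand_covs = covs[:, [pos[t] for t in candidates]]
    model = forward_select(cfg.family, candidates, cand_covs, y_bag)
    return BagModel(bag_idx, oob, subspace, candidates, model)


def train_rglm(
    X: np.ndarray, y: np.ndarray, config: "EnsembleConfig | None" = None
) -> RGLMModel:
    """Train the full ensemble; deterministic given ``(X, y, config.seed)``."""
    config = config or EnsembleConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d (samples x features)")
    n, N = X.shape
    if N == 0:
        raise ValueError("X has no features")
    if y.shape[0] != n:
        raise ValueError("X and y lengths differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X/y contain missing or non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("outcome is constant")
    cfg = config.resolved(N)
    if cfg.family is Family.BINOMIAL and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial outcome must be coded 0/1")

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_bags)
    bags = [
        fit_bag(X, y, cfg, np.random.Generator(np.random.PCG64(s)))
        for s in streams
    ]
    summary = float(y.mean())
    names = [f"F{j}" for j in range(N)]
    return RGLMModel(cfg, bags, n, N, names, summary)


# ---------------------------------------------------------------------------
# prediction and OOB estimation
# ---------------------------------------------------------------------------

def bag_response(bag: BagModel, X: np.ndarray, family: Family) -> np.ndarray:
    """One bag's prediction on the response scale (probability for binomial,
    linear prediction for gaussian)."""
    coefs = bag.model.fit.coefficients
    eta = np.full(X.shape[0], coefs["intercept"], dtype=float)
    if bag.model.selected_terms:
        covs = term_covariates(X, bag.model.selected_terms)
        beta = np.array([coefs[t] for t in bag.model.selected_terms])
        eta += covs @ beta
    if family is Family.BINOMIAL:
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return eta


def predict(model: RGLMModel, X_new: np.ndarray, output: str = "response") -> np.ndarray:
    """Ensemble prediction: mean of per-bag responses; ``output='class'``
    thresholds the averaged probability at ``classify_threshold`` (>= wins)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new must have {model.n_features} features, got shape {X_new.shape}"
        )
    fam = model.config.family
    if output not in ("prob", "class", "response"):
        raise ValueError("output must be 'prob', 'class' or 'response'")
    if output == "prob" and fam is not Family.BINOMIAL:
        raise ValueError("'prob' output requires a binomial model")
    agg = np.zeros(X_new.shape[0])
    for bag in model.bags:
        agg += bag_response(bag, X_new, fam)
    agg /= len(model.bags)
    if output == "class":
        if fam is not Family.BINOMIAL:
            raise ValueError("'class' output requires a binomial model")
        return (agg >= model.config.classify_threshold).astype(int)
    return agg


def oob_predict(model: RGLMModel, X_train: np.ndarray, y_train: np.ndarray):
    """Out-of-bag predictions and the OOB accuracy estimate.

    Each sample's prediction aggregates only the bags in which it was
    out-of-bag; samples that are never OOB are NaN and excluded from the
    accuracy.  Binomial accuracy is 1 minus the misclassification rate at the
    configured threshold; gaussian accuracy is the Pearson correlation of OOB
    predictions with the observed outcome.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = X_train.shape[0]
    fam = model.config.family
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for bag in model.bags:
        oob = bag.oob_indices
        if len(oob) == 0:
            continue
        total[oob] += bag_response(bag, X_train[oob], fam)
        count[oob] += 1
    pred = np.full(n, np.nan)
    have = count > 0
    pred[have] = total[have] / count[have]
    if not have.any():
        return pred, float("nan")
    if fam is Family.BINOMIAL:
        cls = (pred[have] >= model.config.classify_threshold).astype(float)
        acc = float(np.mean(cls == y_train[have]))
    else:
        p, t = pred[have], y_train[have]
        if p.std() == 0 or t.std() == 0:
            acc = float("nan")
        else:
            acc = float(np.corrcoef(p, t)[0, 1])
    return pred, acc
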