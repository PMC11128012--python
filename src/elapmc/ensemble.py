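"""EL-APMC: bagged random-subspace discriminants fused by an adaptive power mean.

The ensemble draws N bootstrap subsets *without replacement*: each subset is
a random half-and-half split of the training data into disjoint InBag and
OutBag index sets (duplicate subsets may occur across the ensemble, never
within one). Each base learner is a two-class linear discriminant trained on
its InBag rows restricted to a random feature subspace of size
round(sqrt(NoF)). Base outputs are positive-class posterior scores clipped
to (0, 1).

Decision fusion uses the power mean combiner (PMC)

    f_alpha(k_1..k_N) = ((1/N) sum_i k_i^alpha)^(1/alpha),

which sweeps from the minimum rule (alpha -> -inf) through harmonic
(alpha = -1), geometric (alpha -> 0) and arithmetic (alpha = 1) means up to
the maximum rule (alpha -> +inf). The exponent alpha and the decision
threshold mu are fitted jointly by minimizing the two-class threshold error

    P_e(alpha, mu) = P(w_hi) F_hi(mu) + P(w_lo) (1 - F_lo(mu))

on the aggregated OutBag fused scores, where w_hi is the class whose fused
scores have the larger mean, F_j its empirical CDF and the priors are the
OutBag class frequencies. A derivative-free global optimizer searches
(alpha, mu); the arithmetic-mean combiner (alpha = 1) with its best
threshold is always a candidate, so the fitted combiner can only improve on
plain score averaging as measured on the OutBag data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.special import logsumexp

from .exceptions import (
    ConfigError,
    DomainError,
    SchemaError,
    ValidationError,
    VersionError,
)

SCORE_EPS = 1e-6
MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# configuration and model containers


@dataclasses.dataclass
class EnsembleConfig:
    """Tunable parameters of the EL-APMC ensemble.

    n_estimators
        Number of base classifiers N (default 100).
    inbag_fraction
        Fraction of the training data forming each InBag half (default 0.5;
        the OutBag half takes the complementary fraction, odd leftovers are
        dropped from that subset).
    subspace_size
        Features per base learner; None means round(sqrt(NoF)) clamped to
        [1, NoF].
    alpha_bounds
        Search interval for the power-mean exponent. Beyond ~|20| the power
        mean is numerically the min/max rule on clipped scores.
    optimizer_budget
        Objective-evaluation budget for the joint (alpha, mu) search.
    use_weights
        If True, fuse with a weighted power mean, weights proportional to
        each base learner's OutBag accuracy.
    """

    n_estimators: int = 100
    inbag_fraction: float = 0.5
    subspace_size: int | None = None
    base_learner: str = "linear_discriminant"
    alpha_bounds: tuple[float, float] = (-20.0, 20.0)
    optimizer_budget: int = 200
    seed: int = 0
    use_weights: bool = False
    max_bag_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be >= 1")
        if not (0.0 < self.inbag_fraction < 1.0):
            raise ConfigError("inbag_fraction must lie in (0, 1)")
        lo, hi = self.alpha_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError("alpha_bounds must be a finite interval lo < hi")
        if self.base_learner != "linear_discriminant":
            raise ConfigError(f"unsupported base learner {self.base_learner!r}")


@dataclasses.dataclass
class BaseModel:
    """One trained base discriminant and its bag bookkeeping."""

    feature_subset: np.ndarray  # column indices into the full feature matrix
    inbag_idx: np.ndarray
    outbag_idx: np.ndarray
    coef: np.ndarray  # discriminant direction over the subspace
    intercept: float
    weight: float = 1.0  # OutBag accuracy

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class posterior scores on the rows of X, clipped to (0,1)."""
        from scipy.special import expit

        d = X[:, self.feature_subset] @ self.coef + self.intercept
        return np.clip(expit(d), SCORE_EPS, 1.0 - SCORE_EPS)


@dataclasses.dataclass
class ClassScoreDistribution:
    """Histogram summary of one class's fused OutBag scores.

    Bin width follows the Freedman–Diaconis rule with a floor of 10 bins;
    the CDF interpolates linearly between bin edges. This is the reported
    per-class score distribution; the threshold-error objective itself uses
    the exact empirical CDF (see :func:`estimate_pe`).
    """

    class_id: int
    mean: float
    std: float
    bin_edges: np.ndarray
    counts: np.ndarray

    @classmethod
    def from_scores(cls, scores: np.ndarray, class_id: int) -> "ClassScoreDistribution":
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            raise DomainError("empty class: score distribution undefined")
        lo, hi = float(scores.min()), float(scores.max())
        iqr = float(np.subtract(*np.percentile(scores, [75, 25])))
        width = 2.0 * iqr / max(scores.size, 1) ** (1 / 3)
        if hi > lo and width > 0:
            n_bins = max(10, int(np.ceil((hi - lo) / width)))
        else:
            n_bins = 10
        counts, edges = np.histogram(scores, bins=n_bins, range=(min(lo, hi - 1e-12), max(hi, lo + 1e-12)))
        return cls(
            class_id=int(class_id),
            mean=float(scores.mean()),
            std=float(scores.std(ddof=0)),
            bin_edges=edges,
            counts=counts,
        )

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        cum = np.concatenate([[0.0], np.cumsum(self.counts)]) / max(self.counts.sum(), 1)
        return np.interp(x, self.bin_edges, cum, left=0.0, right=1.0)


@dataclasses.dataclass
class PMCParams:
    """Fitted fusion parameters: exponent, threshold, priors, distributions."""

    alpha_opt: float
    mu_opt: float
    priors: tuple[float, float]  # (P(w_lo), P(w_hi)) in label order (0, 1)
    hi_class: int  # internal class (0/1) with the larger fused-score mean
    achieved_pe: float
    dists: tuple[ClassScoreDistribution, ClassScoreDistribution] | None = None


@dataclasses.dataclass
class ElapmcModel:
    """A fully trained EL-APMC ensemble."""

    config: EnsembleConfig
    base_models: list[BaseModel]
    pmc: PMCParams
    feature_names: list[str]
    classes: list  # [negative_label, positive_label]
    positive_class: object
    weights: np.ndarray | None = None  # normalized fusion weights if use_weights


# ---------------------------------------------------------------------------
# bagging and subspace sampling


def make_bags(
    n_samples: int, config: EnsembleConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw N disjoint (InBag, OutBag) index pairs without replacement.

    Each bootstrap subset is a seeded permutation of the sample indices cut
    into an InBag of floor(n * inbag_fraction) rows and an OutBag of
    floor(n * (1 - inbag_fraction)) rows; leftover rows are dropped from
    that subset only.
    """
    n_in = int(np.floor(n_samples * config.inbag_fraction))
    n_out = int(np.floor(n_samples * (1.0 - config.inbag_fraction)))
    if n_in < 1 or n_out < 1:
        raise ConfigError(
            f"n_samples={n_samples} too small for inbag_fraction="
            f"{config.inbag_fraction}: both halves must be non-empty"
        )
    bags = []
    for _ in range(config.n_estimators):
        perm = rng.permutation(n_samples)
        bags.append((np.sort(perm[:n_in]), np.sort(perm[n_in : n_in + n_out])))
    return bags


def subspace_size(n_features: int, config: EnsembleConfig | None = None) -> int:
    """round(sqrt(NoF)) with half-up rounding, clamped to [1, NoF]."""
    if config is not None and config.subspace_size is not None:
        return int(np.clip(config.subspace_size, 1, n_features))
    m = int(np.floor(np.sqrt(n_features) + 0.5))
    return int(np.clip(m, 1, n_features))


def pick_subspace(
    n_features: int, config: EnsembleConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random feature index subset of size round(sqrt(NoF))."""
    if n_features < 1:
        raise ConfigError("need at least one feature")
    m = subspace_size(n_features, config)
    return np.sort(rng.choice(n_features, size=m, replace=False))


# ---------------------------------------------------------------------------
# base learner


def fit_base(X_inbag: np.ndarray, y_inbag: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit a two-class linear discriminant; returns (coef, intercept).

    Scores are posterior probabilities of class 1 obtained from the logistic
    of the discriminant function. Ledoit–Wolf shrinkage keeps the pooled
    covariance invertible on small or degenerate (constant-column) bags.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    if len(np.unique(y_inbag)) < 2:
        raise DomainError("InBag contains a single class")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(X_inbag, y_inbag)
    coef = lda.coef_[0].astype(float)
    intercept = float(lda.intercept_[0])
    if lda.classes_[1] != 1:  # orient toward internal positive class 1
        coef, intercept = -coef, -intercept
    return coef, intercept


# ---------------------------------------------------------------------------
# power mean combiner


def pmc_fuse(
    scores: np.ndarray,
    alpha: float,
    weights: Sequence[float] | None = None,
    axis: int = -1,
) -> np.ndarray | float:
    """Power mean of positive scores along ``axis``.

    ``alpha=1`` is the arithmetic mean, ``alpha=-1`` harmonic, ``|alpha| <
    1e-6`` is evaluated as the geometric-mean limit exp(mean(log k)). The
    output always lies within [min k, max k]. Computed in log space so large
    |alpha| neither overflows nor underflows.
    """
    k = np.asarray(scores, dtype=float)
    if np.any(k <= 0):
        raise DomainError("power mean requires strictly positive scores")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise DomainError("weights must be non-negative with positive sum")
        w = w / w.sum()
    else:
        w = np.full(k.shape[axis], 1.0 / k.shape[axis])
    logk = np.log(k)
    if abs(alpha) < 1e-6:  # geometric-mean limit
        out = np.exp(np.sum(logk * _shape_for(w, k.ndim, axis), axis=axis))
    else:
        lse = logsumexp(alpha * logk, b=_shape_for(w, k.ndim, axis), axis=axis)
        out = np.exp(lse / alpha)
    return float(out) if np.ndim(out) == 0 else out


def _shape_for(w: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = w.size
    return w.reshape(shape)


# ---------------------------------------------------------------------------
# threshold error


def estimate_pe(
    mu: float,
    fused_scores: np.ndarray,
    labels: np.ndarray,
    hi_class: int | None = None,
    priors: tuple[float, float] | None = None,
) -> float:
    """Two-class threshold error of the rule "hi class iff score >= mu".

    P_e = P(w_hi) F_hi(mu) + P(w_lo) (1 - F_lo(mu)) with F_j the exact
    empirical CDFs (fraction of class-j scores strictly below mu; ties at mu
    go to the hi class). With priors equal to the empirical class
    frequencies this is exactly the empirical misclassification rate.

    ``hi_class`` (the class whose scores should exceed mu) defaults to the
    class with the larger mean fused score.
    """
    fused = np.asarray(fused_scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise DomainError("estimate_pe needs exactly two classes present")
    if hi_class is None:
        m0 = fused[labels == classes[0]].mean()
        m1 = fused[labels == classes[1]].mean()
        hi_class = classes[1] if m1 >= m0 else classes[0]
    lo_class = classes[0] if hi_class == classes[1] else classes[1]
    hi = fused[labels == hi_class]
    lo = fused[labels == lo_class]
    if priors is None:
        n = fused.size
        p_hi, p_lo = hi.size / n, lo.size / n
    else:
        p_lo, p_hi = priors
    f_hi = np.mean(hi < mu)  # hi scored below threshold -> error
    s_lo = np.mean(lo >= mu)  # lo at/above threshold -> error (ties to hi)
    return float(p_hi * f_hi + p_lo * s_lo)


def _best_mu(fused: np.ndarray, labels: np.ndarray, hi_class: int) -> tuple[float, float]:
    """Exact best threshold for fixed fused scores (vectorized cut scan)."""
    hi = np.sort(fused[labels == hi_class])
    lo = np.sort(fused[labels != hi_class])
    n = fused.size
    s = np.unique(fused)
    # candidate thresholds: below all scores, at each score, above all scores
    cand = np.concatenate([[s[0] - 1e-9], s, [s[-1] + 1e-9]])
    n_hi_below = np.searchsorted(hi, cand, side="left")
    n_lo_at_or_above = lo.size - np.searchsorted(lo, cand, side="left")
    errs = (n_hi_below + n_lo_at_or_above) / n  # empirical-prior threshold error
    i = int(np.argmin(errs))
    return float(cand[i]), float(errs[i])


# ---------------------------------------------------------------------------
# joint (alpha, mu) optimization


def optimize_pmc(
    outbag_scores: np.ndarray,
    labels: np.ndarray,
    config: EnsembleConfig,
    weights: Sequence[float] | None = None,
) -> PMCParams:
    """Jointly fit the power-mean exponent and decision threshold.

    Minimizes the OutBag threshold error over alpha_bounds x (0, 1) with
    seeded differential evolution (derivative-free, global), then refines mu
    exactly at the best exponent found and at alpha = 1. The arithmetic-mean
    candidate guarantees the fitted combiner never does worse on OutBag data
    than plain score averaging.
    """
    if config.optimizer_budget < 10:
        raise ConfigError("optimizer_budget must be at least 10 evaluations")
    S = np.asarray(outbag_scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise DomainError("OutBag aggregation must contain both classes")
    n = labels.size
    classes = np.unique(labels)
    p = np.array([(labels == c).mean() for c in classes])

    def orientation(alpha: float) -> tuple[np.ndarray, int]:
        fused = pmc_fuse(S, alpha, weights=weights, axis=1)
        m0 = fused[labels == classes[0]].mean()
        m1 = fused[labels == classes[1]].mean()
        return fused, (classes[1] if m1 >= m0 else classes[0])

    def objective(x: np.ndarray) -> float:
        fused, hi = orientation(float(x[0]))
        return estimate_pe(float(x[1]), fused, labels, hi)

    lo, hi_b = config.alpha_bounds
    popsize = 8
    # DE spends ~ popsize * dim evaluations per generation (dim = 2)
    maxiter = max(1, config.optimizer_budget // (popsize * 2) - 1)
    res = differential_evolution(
        objective,
        bounds=[(lo, hi_b), (SCORE_EPS, 1.0 - SCORE_EPS)],
        seed=int(config.seed) % (2**31),
        maxiter=maxiter,
        popsize=popsize,
        init="sobol",
        polish=False,
        tol=1e-12,
    )
    alpha_de = float(res.x[0])

    # exact mu refinement at the DE exponent and at the arithmetic mean
    fused_de, hi_de = orientation(alpha_de)
    mu_de, pe_de = _best_mu(fused_de, labels, hi_de)
    fused_1, hi_1 = orientation(1.0)
    mu_1, pe_1 = _best_mu(fused_1, labels, hi_1)

    if pe_de <= pe_1:
        alpha_opt, mu_opt, pe_opt, hi_cls = alpha_de, mu_de, pe_de, hi_de
    else:
        alpha_opt, mu_opt, pe_opt, hi_cls = 1.0, mu_1, pe_1, hi_1

    fused_opt, _ = orientation(alpha_opt)
    dists = tuple(
        ClassScoreDistribution.from_scores(fused_opt[labels == c], int(c))
        for c in classes
    )
    return PMCParams(
        alpha_opt=alpha_opt,
        mu_opt=float(np.clip(mu_opt, SCORE_EPS, 1.0 - SCORE_EPS)),
        priors=(float(p[0]), float(p[1])),
        hi_class=int(hi_cls),
        achieved_pe=pe_opt,
        dists=dists,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# fit / predict


def _as_matrix(
    X, feature_names: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    names = feature_names or [f"f{i}" for i in range(arr.shape[1])]
    return arr, names


def fit(
    X,
    y,
    config: EnsembleConfig | None = None,
    positive_class: object = None,
) -> ElapmcModel:
    """Train an EL-APMC ensemble on a feature table.

    ``positive_class`` names the label whose posterior each base classifier
    scores (defaults to the larger label value). Fully deterministic under
    ``config.seed``.
    """
    config = config or EnsembleConfig()
    Xm, feature_names = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[0] != y.size:
        raise SchemaError("X and y have mismatched lengths")
    if np.isnan(Xm).any():
        raise ValidationError("missing feature values are not supported")
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise DomainError(f"need exactly 2 classes, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise DomainError(f"positive_class {positive_class!r} not in labels")
    negative_class = classes[0] if classes[1] == positive_class else classes[1]
    yb = (y == positive_class).astype(int)  # internal 0/1 coding
    counts = np.bincount(yb, minlength=2)
    if counts.min() < 2:
        raise DomainError("need at least 2 samples per class")

    rng = np.random.default_rng(config.seed)
    n, nof = Xm.shape
    bags = make_bags(n, config, rng)

    base_models: list[BaseModel] = []
    for inbag, outbag in bags:
        subset = pick_subspace(nof, config, rng)
        retries = 0
        while np.unique(yb[inbag]).size < 2:
            if retries >= config.max_bag_retries:
                raise DomainError(
                    "could not draw a two-class InBag after "
                    f"{config.max_bag_retries} retries"
                )
            perm = rng.permutation(n)
            n_in, n_out = inbag.size, outbag.size
            inbag = np.sort(perm[:n_in])
            outbag = np.sort(perm[n_in : n_in + n_out])
            retries += 1
        coef, intercept = fit_base(Xm[inbag][:, subset], yb[inbag])
        model = BaseModel(
            feature_subset=subset,
            inbag_idx=inbag,
            outbag_idx=outbag,
            coef=coef,
            intercept=intercept,
        )
        ob_scores = model.scores(Xm[outbag])
        model.weight = float(np.mean((ob_scores >= 0.5).astype(int) == yb[outbag]))
        base_models.append(model)

    # aggregate every OutBag replica (no deduplication) and score it with
    # the full ensemble: rows = OutBag occurrences, cols = base classifiers
    agg_idx = np.concatenate([m.outbag_idx for m in base_models])
    S = np.column_stack([m.scores(Xm[agg_idx]) for m in base_models])
    weights = None
    if config.use_weights:
        weights = np.array([m.weight for m in base_models], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        weights = weights / weights.sum()
    pmc = optimize_pmc(S, yb[agg_idx], config, weights=weights)
    return ElapmcModel(
        config=config,
        base_models=base_models,
        pmc=pmc,
        feature_names=feature_names,
        classes=[negative_class, positive_class],
        positive_class=positive_class,
        weights=weights,
    )


def predict_score(model: ElapmcModel, X) -> np.ndarray:
    """Fused ensemble score per row of X at the fitted exponent."""
    Xm, names = _as_matrix(X, model.feature_names)
    if names != model.feature_names:
        raise SchemaError(
            f"feature mismatch: model expects {model.feature_names}, got {names}"
        )
    if Xm.shape[1] != len(model.feature_names):
        raise SchemaError("feature count mismatch")
    S = np.column_stack([m.scores(Xm) for m in model.base_models])
    return np.asarray(
        pmc_fuse(S, model.pmc.alpha_opt, weights=model.weights, axis=1)
    )


def predict(model: ElapmcModel, X) -> np.ndarray:
    """Class labels: the high-score class iff fused score >= mu_opt."""
    fused = predict_score(model, X)
    hi_label = model.classes[model.pmc.hi_class]
    lo_label = model.classes[1 - model.pmc.hi_class]
    out = np.where(fused >= model.pmc.mu_opt, hi_label, lo_label)
    return out.astype(type(hi_label)) if np.isscalar(hi_label) else out


# ---------------------------------------------------------------------------
# serialization


def save_model(model: ElapmcModel, path: str | os.PathLike) -> None:
    """Serialize a trained model to versioned JSON (lossless round-trip)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "feature_names": model.feature_names,
        "classes": model.classes,
        "positive_class": model.positive_class,
        "weights": None if model.weights is None else model.weights.tolist(),
        "pmc": {
            "alpha_opt": model.pmc.alpha_opt,
            "mu_opt": model.pmc.mu_opt,
            "priors": list(model.pmc.priors),
            "hi_class": model.pmc.hi_class,
            "achieved_pe": model.pmc.achieved_pe,
        },
        "base_models": [
            {
                "feature_subset": m.feature_subset.tolist(),
                "inbag_idx": m.inbag_idx.tolist(),
                "outbag_idx": m.outbag_idx.tolist(),
                "coef": m.coef.tolist(),
                "intercept": m.intercept,
                "weight": m.weight,
            }
            for m in model.base_models
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path: str | os.PathLike) -> ElapmcModel:
    """Inverse of :func:`save_model`; rejects unknown format versions."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise VersionError(
            f"model format version {version!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    cfg_d = dict(doc["config"])
    cfg_d["alpha_bounds"] = tuple(cfg_d["alpha_bounds"])
    config = EnsembleConfig(**cfg_d)
    base_models = [
        BaseModel(
            feature_subset=np.array(m["feature_subset"], dtype=int),
            inbag_idx=np.array(m["inbag_idx"], dtype=int),
            outbag_idx=np.array(m["outbag_idx"], dtype=int),
            coef=np.array(m["coef"], dtype=float),
            intercept=float(m["intercept"]),
            weight=float(m["weight"]),
        )
        for m in doc["base_models"]
    ]
    pmc_d = doc["pmc"]
    pmc = PMCParams(
        alpha_opt=float(pmc_d["alpha_opt"]),
        mu_opt=float(pmc_d["mu_opt"]),
        priors=tuple(pmc_d["priors"]),
        hi_class=int(pmc_d["hi_class"]),
        achieved_pe=float(pmc_d["achieved_pe"]),
    )
    weights = doc.get("weights")
    return ElapmcModel(
        config=config,
        base_models=base_models,
        pmc=pmc,
        feature_names=list(doc["feature_names"]),
        classes=list(doc["classes"]),
        positive_class=doc["positive_class"],
        weights=None if weights is None else np.array(weights, dtype=float),
    )


class ElapmcClassifier:
    """Thin scikit-learn-style estimator wrapper around :func:`fit`/:func:`predict`."""

    def __init__(self, config: EnsembleConfig | None = None, positive_class=None):
        self.config = config
        self.positive_class = positive_class

    def get_params(self, deep: bool = True):
        return {"config": self.config, "positive_class": self.positive_class}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        self.model_ = fit(X, y, self.config, self.positive_class)
        return self

    def predict(self, X):
        return predict(self.model_, X)

    def predict_score(self, X):
        return predict_score(self.model_, X)
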