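"""Synthetic two-class data with the statistical structure the method assumes.

Three generators:

* :func:`gen_features` — per-subject feature tables drawn from two 8-variate
  Gaussians with a shared covariance, then mapped onto the feature
  constraints (non-negative mean-presence columns, ratio columns
  renormalized onto the simplex). For the equal-covariance case the
  underlying Bayes error has the closed form Phi(-Delta/2) with Delta the
  Mahalanobis distance between the class means; the default spec spreads
  the separation evenly over all 8 standardized feature directions (ratio
  shifts summing to zero, so simplex renormalization preserves them).
* :func:`gen_volume` — toy labeled segmentation volumes whose per-class
  descriptor proportions are known exactly, for oracle-testing the feature
  extractor.
* :func:`gen_fusion_testbed` — OutBag-style base-score matrices in regimes
  where particular power-mean exponents are provably optimal, for
  exercising the combiner optimization.

All generators are bit-reproducible under their seeds.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mri_features as mf
from .exceptions import ConfigError, DomainError, ValidationError

LOW_GRADE = "LGG"
HIGH_GRADE = "HGG"


# ---------------------------------------------------------------------------
# feature tables


@dataclasses.dataclass
class FeatureGenSpec:
    """Two-class Gaussian feature generator specification.

    ``mean_low``/``mean_high`` are 8-vectors in the canonical feature order
    (tC_M, tnC_M, Edm_M, Nec_M, tC_R, tnC_R, Edm_R, Nec_R); ``cov`` is the
    shared 8x8 covariance. ``n_per_class`` is (n low-grade, n high-grade);
    the default mimics a ~275-subject cohort with ~80/20 class imbalance.
    """

    n_per_class: tuple[int, int] = (55, 220)
    mean_low: np.ndarray = None  # type: ignore[assignment]
    mean_high: np.ndarray = None  # type: ignore[assignment]
    cov: np.ndarray = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_low is None or self.mean_high is None or self.cov is None:
            built = default_feature_spec(seed=self.seed, n_per_class=self.n_per_class)
            if self.mean_low is None:
                self.mean_low = built.mean_low
            if self.mean_high is None:
                self.mean_high = built.mean_high
            if self.cov is None:
                self.cov = built.cov
        self.mean_low = np.asarray(self.mean_low, dtype=float)
        self.mean_high = np.asarray(self.mean_high, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean_low.shape != (8,) or self.mean_high.shape != (8,):
            raise ConfigError("class means must be 8-vectors")
        if self.cov.shape != (8, 8):
            raise ConfigError("covariance must be 8x8")
        if not np.allclose(self.cov, self.cov.T):
            raise ConfigError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() <= 0:
            raise ConfigError("covariance must be positive-definite")

    @property
    def mahalanobis(self) -> float:
        d = self.mean_high - self.mean_low
        return float(np.sqrt(d @ np.linalg.solve(self.cov, d)))

    @property
    def bayes_error(self) -> float:
        """Closed-form optimal error of the underlying equal-covariance Gaussians."""
        return float(stats.norm.cdf(-self.mahalanobis / 2.0))


def default_feature_spec(
    bayes_error: float = 0.05,
    n_per_class: tuple[int, int] = (55, 220),
    seed: int = 0,
) -> FeatureGenSpec:
    """Build the default spec with a requested closed-form Bayes error.

    The low-grade profile has modest enhancement and necrosis and a large
    edema share; the high-grade shift raises enhancement/necrosis presence
    and shifts composition toward enhancing tumor, with the total
    standardized shift scaled to the Mahalanobis distance implied by
    ``bayes_error``.
    """
    if not (0.0 < bayes_error <= 0.5):
        raise ConfigError("bayes_error must lie in (0, 0.5]")
    delta = float(-2.0 * stats.norm.ppf(bayes_error))
    sd = np.array([6.0, 6.0, 6.0, 6.0, 0.04, 0.04, 0.04, 0.04])
    mean_low = np.array([25.0, 12.0, 45.0, 15.0, 0.26, 0.12, 0.46, 0.16])
    # unit direction in standardized units; ratio shifts sum to zero so the
    # simplex renormalization does not erase them
    direction = np.array([1.0, 1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0])
    direction = direction / np.linalg.norm(direction)
    mean_high = mean_low + delta * direction * sd
    cov = np.diag(sd**2)
    return FeatureGenSpec(
        n_per_class=n_per_class,
        mean_low=mean_low,
        mean_high=mean_high,
        cov=cov,
        seed=seed,
    )


def gen_features(spec: FeatureGenSpec) -> pd.DataFrame:
    """Draw a labeled feature table from the spec's two Gaussians.

    Mean-presence columns are clipped to be non-negative and ratio columns
    renormalized to sum to 1, so every row satisfies the feature-table
    invariants. Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_lo, n_hi = spec.n_per_class
    X_lo = rng.multivariate_normal(spec.mean_low, spec.cov, size=n_lo)
    X_hi = rng.multivariate_normal(spec.mean_high, spec.cov, size=n_hi)
    X = np.vstack([X_lo, X_hi])
    labels = np.array([LOW_GRADE] * n_lo + [HIGH_GRADE] * n_hi)
    X[:, :4] = np.maximum(X[:, :4], 0.0)
    ratios = np.clip(X[:, 4:], 1e-9, None)
    X[:, 4:] = ratios / ratios.sum(axis=1, keepdims=True)
    df = pd.DataFrame(X, columns=list(mf.FEATURE_COLUMNS))
    df.insert(0, "subject_id", [f"synth-{i:04d}" for i in range(len(df))])
    df["label"] = labels
    return df


def monte_carlo_bayes_error(
    spec: FeatureGenSpec, n: int = 200_000, seed: int = 0
) -> float:
    """Error of the optimal (true-parameter) rule on fresh underlying draws.

    Evaluates the equal-covariance likelihood-ratio rule on raw Gaussian
    samples (before the constraint mapping), the quantity the closed form
    describes.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    d = spec.mean_high - spec.mean_low
    w = np.linalg.solve(spec.cov, d)
    c = 0.5 * w @ (spec.mean_high + spec.mean_low)
    X_lo = rng.multivariate_normal(spec.mean_low, spec.cov, size=half)
    X_hi = rng.multivariate_normal(spec.mean_high, spec.cov, size=half)
    err_lo = np.mean(X_lo @ w - c >= 0)
    err_hi = np.mean(X_hi @ w - c < 0)
    return float(0.5 * (err_lo + err_hi))


# ---------------------------------------------------------------------------
# segmentation volumes


@dataclasses.dataclass
class VolumeGenSpec:
    """Toy segmentation-volume generator specification.

    ``proportions`` maps a class id to its target descriptor composition
    (tC, tnC, Edm, Nec), each summing to 1. Tumor occupies
    ``n_tumor_slices`` consecutive central slices with ``voxels_per_slice``
    tumor voxels each.
    """

    dims: tuple[int, int, int] = (24, 24, 10)
    n_tumor_slices: int = 6
    voxels_per_slice: int = 300
    proportions: Mapping[object, tuple[float, float, float, float]] = dataclasses.field(
        default_factory=lambda: {
            LOW_GRADE: (0.10, 0.20, 0.50, 0.20),
            HIGH_GRADE: (0.40, 0.15, 0.25, 0.20),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, p in self.proportions.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"proportions for {cls!r} must lie on the simplex")
        if self.n_tumor_slices < 1 or self.n_tumor_slices > self.dims[2]:
            raise ConfigError("n_tumor_slices must fit within the volume depth")
        if self.voxels_per_slice > self.dims[0] * self.dims[1]:
            raise ConfigError("voxels_per_slice exceeds slice capacity")


def _apportion(total: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder integer apportionment of ``total`` over proportions."""
    raw = proportions * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def gen_volume(
    spec: VolumeGenSpec,
    class_id,
    seed: int | None = None,
    deterministic: bool = False,
) -> tuple[mf.SegmentationVolume, mf.FeatureVector]:
    """Generate one labeled volume plus its exact ground-truth features.

    In deterministic mode every tumor slice carries the exact
    largest-remainder apportionment of the target proportions, placed in
    raster order; in random mode per-slice descriptor counts are
    multinomial draws and placement is a random subset of slice positions.
    The returned feature vector is hand-counted from the actually placed
    voxels, so it is exact in both modes.
    """
    if class_id not in spec.proportions:
        raise DomainError(f"unknown class {class_id!r}")
    p = np.asarray(spec.proportions[class_id], dtype=float)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nx, ny, nz = spec.dims
    labels = np.zeros(spec.dims, dtype=np.int16)
    lm = mf.DEFAULT_LABEL_MAP
    # descriptor label values in (tC, tnC, Edm, Nec) order
    stems = [lm["enhancing"], lm["non_enhancing"], lm["edema"], lm["necrosis"]]
    z0 = (nz - spec.n_tumor_slices) // 2
    totals = np.zeros(4, dtype=int)
    for s in range(spec.n_tumor_slices):
        if deterministic:
            counts = _apportion(spec.voxels_per_slice, p)
            positions = np.arange(spec.voxels_per_slice)
        else:
            counts = rng.multinomial(spec.voxels_per_slice, p)
            positions = rng.choice(nx * ny, size=spec.voxels_per_slice, replace=False)
        totals += counts
        flat = np.zeros(nx * ny, dtype=np.int16)
        start = 0
        for lbl, c in zip(stems, counts):
            flat[positions[start : start + c]] = lbl
            start += c
        labels[:, :, z0 + s] = flat.reshape(nx, ny)
    volume = mf.SegmentationVolume(labels, dict(lm))
    means = totals / spec.n_tumor_slices
    ratios = totals / totals.sum()
    truth = mf.FeatureVector(
        subject_id=f"synth-{class_id}",
        tC_M=means[0],
        tnC_M=means[1],
        Edm_M=means[2],
        Nec_M=means[3],
        tC_R=ratios[0],
        tnC_R=ratios[1],
        Edm_R=ratios[2],
        Nec_R=ratios[3],
        label=class_id,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# fusion testbed


def gen_fusion_testbed(
    n: int,
    n_base: int,
    regime: str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """OutBag-style base-score matrices exercising the combiner optimization.

    Regimes
    -------
    ``identical``
        One informative score column duplicated across all bases: the power
        mean is then independent of the exponent.
    ``independent``
        Conditionally independent informative bases (logistic of a class
        signal plus noise): averaging should beat a single base.
    ``outlier-min``
        Positive samples score uniformly in (0.52, 0.60) on every base;
        negative samples score in (0.40, 0.48) except for one uniformly
        placed contaminant base in (0.92, 0.98). The minimum rule separates
        the classes perfectly while the arithmetic mean overlaps, so a
        strongly negative exponent is optimal by construction. The info
        dict reports the brute-force best threshold errors at alpha = 1 and
        at a min-like alpha and their margin.
    """
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    labels = np.array([0] * n_neg + [1] * n_pos)
    if regime == "identical":
        col = np.where(
            labels == 1, rng.uniform(0.6, 0.9, size=n), rng.uniform(0.1, 0.4, size=n)
        )
        S = np.tile(col[:, None], (1, n_base))
        info = {}
    elif regime == "independent":
        z = np.where(labels == 1, 0.8, -0.8)
        noise = rng.normal(0.0, 1.2, size=(n, n_base))
        S = 1.0 / (1.0 + np.exp(-(z[:, None] + noise)))
        S = np.clip(S, 1e-6, 1 - 1e-6)
        info = {}
    elif regime == "outlier-min":
        S = np.empty((n, n_base))
        S[labels == 1] = rng.uniform(0.52, 0.60, size=(n_pos, n_base))
        neg = rng.uniform(0.40, 0.48, size=(n_neg, n_base))
        contam_col = rng.integers(0, n_base, size=n_neg)
        neg[np.arange(n_neg), contam_col] = rng.uniform(0.92, 0.98, size=n_neg)
        S[labels == 0] = neg
        from .ensemble import _best_mu, pmc_fuse

        fused_1 = np.asarray(pmc_fuse(S, 1.0, axis=1))
        fused_lo = np.asarray(pmc_fuse(S, -20.0, axis=1))
        _, pe_1 = _best_mu(fused_1, labels, hi_class=1)
        _, pe_lo = _best_mu(fused_lo, labels, hi_class=1)
        info = {
            "pe_alpha1": pe_1,
            "pe_low_alpha": pe_lo,
            "margin": pe_1 - pe_lo,
        }
    else:
        raise DomainError(
            f"unknown regime {regime!r}; one of identical/independent/outlier-min"
        )
    return S, labels, info
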