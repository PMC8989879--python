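"""The scalar-projection prognostic index and cohort stratification.

A trained GMLVQ model defines a prognostic axis: the line from the
Clinically Stable prototype to the Clinically Declining prototype in the
learnt metric space.  Each subject's feature vector is mapped into that
space with the symmetric square root of the metric tensor,

    X = Lambda^{1/2} x,     W_s = Lambda^{1/2} w_s,   W_d = Lambda^{1/2} w_d,

and the prognostic index is the normalized orthogonal projection onto the
axis,

    s = <X - W_s, W_d - W_s> / ||W_d - W_s||^2,

so s = 0 at the Stable prototype and s = 1 at the Declining prototype,
with no range restriction beyond that anchoring.  A three-class logistic
model of diagnosis class on s locates the probabilistic boundary where an
individual becomes less than 50% likely to be Clinically Stable; subjects
with s strictly greater than that threshold are stratified as Clinically
Declining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.discrete.discrete_model import MNLogit

from .gmlvq import GMLVQ, GMLVQResults
from .tables import CLASS_ACS, CLASS_DECLINING, CLASS_STABLE, FEATURE_COLUMNS

__all__ = [
    "sqrt_psd", "transform_to_metric_space", "scalar_projection",
    "ThresholdModel", "fit_threshold", "stratify",
    "CVResult", "balanced_resampling_cv",
]


def sqrt_psd(lam: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues below zero (numerical noise) are clipped at 0.  Raises if
    the input is asymmetric beyond *tol*.
    """
    lam = np.asarray(lam, dtype=float)
    if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
        raise ValueError("metric tensor must be square")
    if np.max(np.abs(lam - lam.T)) > tol:
        raise ValueError("metric tensor is not symmetric")
    vals, vecs = np.linalg.eigh((lam + lam.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def transform_to_metric_space(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Map vectors into the learnt space: Lambda^{1/2} x (row-wise)."""
    root = sqrt_psd(lam)
    x = np.asarray(x, dtype=float)
    return x @ root.T  # root symmetric, but keep the convention explicit


def scalar_projection(X, results: GMLVQResults) -> np.ndarray:
    """Prognostic index s for raw-unit feature vectors.

    The model's scaler is applied, both sample and prototypes are mapped
    through Lambda^{1/2}, and s is the projection onto the
    Stable->Declining prototype axis normalized by its squared length.
    """
    X = np.asarray(X, dtype=float)
    scalar_input = X.ndim == 1
    Z = results.standardize(X)
    root = sqrt_psd(results.lambda_)
    Zm = Z @ root.T
    Ws = results.prototypes[0] @ root.T
    Wd = results.prototypes[1] @ root.T
    axis = Wd - Ws
    denom = float(axis @ axis)
    if denom <= 0:
        raise ValueError("coincident prototypes: prognostic axis undefined")
    s = (Zm - Ws) @ axis / denom
    return float(s[0]) if scalar_input else s


# ---------------------------------------------------------------------------
# probabilistic classification boundary

_THREE_CLASSES = (CLASS_STABLE, CLASS_DECLINING, CLASS_ACS)


@dataclass
class ThresholdModel:
    """Three-class logistic model of diagnosis class on the index s.

    ``threshold_s`` is where P(Clinically Stable | s) crosses 0.5; with
    complete separation the logistic fit is degenerate and the threshold is
    the midpoint of the empirical gap (``separated`` flag set).
    """

    threshold_s: float
    params: pd.DataFrame | None  # rows (const, s), one column per non-reference class
    classes: tuple = _THREE_CLASSES
    separated: bool = False

    def stable_probability(self, s) -> np.ndarray:
        """P(Clinically Stable | s) under the fitted multinomial model."""
        s = np.asarray(s, dtype=float)
        if self.params is None:  # separated: step function at the threshold
            return np.where(s <= self.threshold_s, 1.0, 0.0)
        logits = np.stack([
            self.params.loc["const", c] + self.params.loc["s", c] * s
            for c in self.params.columns
        ])
        denom = 1.0 + np.exp(logits).sum(axis=0)
        return 1.0 / denom


def fit_threshold(scores, labels, classes=_THREE_CLASSES) -> ThresholdModel:
    """Fit the probabilistic boundary on the index.

    Multinomial logistic regression (Clinically Stable as reference) of the
    three-class diagnosis on s, then bisection for the s where
    P(Stable | s) = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    missing = set(classes) - present
    if missing:
        raise ValueError(f"all three classes required; missing {sorted(missing)}")

    stable = s[labels == classes[0]]
    rest = s[labels != classes[0]]
    if stable.max() < rest.min():
        gap_mid = float((stable.max() + rest.min()) / 2.0)
        warnings.warn("complete separation of Clinically Stable scores; "
                      "threshold set to the midpoint of the empirical gap")
        return ThresholdModel(gap_mid, None, tuple(classes), separated=True)

    # integer codes keep the reference category = Clinically Stable
    code = {c: k for k, c in enumerate(classes)}
    endog = np.array([code[l] for l in labels])
    exog = pd.DataFrame({"const": np.ones_like(s), "s": s})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MNLogit(endog, exog).fit(method="newton", maxiter=200, disp=0)
    params = pd.DataFrame(np.asarray(fit.params), index=["const", "s"],
                          columns=list(classes[1:]))
    model = ThresholdModel(np.nan, params, tuple(classes))

    lo, hi = float(s.min()) - 1.0, float(s.max()) + 1.0
    f = lambda v: model.stable_probability(v) - 0.5
    # widen until the crossing is bracketed (P is strictly decreasing in s
    # whenever the non-reference slopes are positive)
    for _ in range(60):
        if f(lo) > 0 and f(hi) < 0:
            break
        lo, hi = lo - abs(lo) - 1.0, hi + abs(hi) + 1.0
    else:
        raise ValueError("stable-class probability does not cross 0.5")
    model.threshold_s = float(optimize.bisect(f, lo, hi, xtol=1e-8))
    return model


def stratify(scores, threshold: float) -> np.ndarray:
    """Assign Clinically Declining iff s > threshold (strict), else Stable."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.where(s > threshold, CLASS_DECLINING, CLASS_STABLE)


# ---------------------------------------------------------------------------
# balanced resampling cross-validation

@dataclass
class CVResult:
    """Per-resample sensitivity/specificity and the class-balanced accuracy.

    Sensitivity is the true-positive rate with Clinically Declining as the
    positive class; balanced accuracy is the mean over resamples of
    (TPR + TNR)/2.
    """

    sensitivity: np.ndarray
    specificity: np.ndarray
    n_resamples: int
    positive_class: str = CLASS_DECLINING
    train_meta: dict = field(default_factory=dict)

    @property
    def balanced_accuracy(self) -> float:
        return float(np.mean((self.sensitivity + self.specificity) / 2.0))

    def summary(self) -> str:
        return (
            f"Balanced resampling CV ({self.n_resamples} resamples)\n"
            f"  balanced accuracy: {self.balanced_accuracy:.3f}\n"
            f"  sensitivity ({self.positive_class}): "
            f"{self.sensitivity.mean():.3f}\n"
            f"  specificity: {self.specificity.mean():.3f}"
        )


def balanced_resampling_cv(cohort: pd.DataFrame, n_resamples: int = 400,
                           seed: int = 0, features=FEATURE_COLUMNS,
                           class_names=(CLASS_STABLE, CLASS_DECLINING),
                           **train_kwargs) -> CVResult:
    """Class-balanced random-resampling cross-validation of the classifier.

    Each resample draws floor(n_minority / 2) subjects from the minority
    class and the same number from the majority class as a balanced
    training set; all remaining subjects are the test set.  Sensitivity and
    specificity are computed per resample and averaged.
    """
    sub = cohort[cohort["class_label"].isin(class_names)]
    X = sub[list(features)].to_numpy(float)
    y = sub["class_label"].to_numpy()
    counts = {c: int((y == c).sum()) for c in class_names}
    n_min = min(counts.values())
    if n_min < 4:
        raise ValueError(f"minority class too small for resampling: {counts}")
    per_class = n_min // 2

    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(y == c) for c in class_names}
    pos = class_names[1]

    sens = np.empty(n_resamples)
    spec = np.empty(n_resamples)
    for b in range(n_resamples):
        train_idx = np.concatenate([
            rng.choice(idx_by_class[c], size=per_class, replace=False)
            for c in class_names
        ])
        mask = np.zeros(len(y), dtype=bool)
        mask[train_idx] = True
        res = GMLVQ(X[mask], y[mask], class_names=class_names).fit(
            seed=seed, **train_kwargs)
        pred = res.classify(X[~mask])
        truth = y[~mask]
        is_pos = truth == pos
        sens[b] = np.mean(pred[is_pos] == pos) if is_pos.any() else np.nan
        spec[b] = np.mean(pred[~is_pos] != pos) if (~is_pos).any() else np.nan
    return CVResult(sens, spec, n_resamples,
                    train_meta={"per_class_train": per_class, "counts": counts,
                                "seed": int(seed)})
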