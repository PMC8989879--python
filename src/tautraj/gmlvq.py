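"""Generalised Matrix Learning Vector Quantisation (GMLVQ).

A two-class prototype classifier with a full, trainable metric tensor.
Each class k is represented by a prototype w_k in (standardized) feature
space; distances are measured with the quadratic form

    d_Lambda(x, w) = (x - w)' Lambda (x - w),      Lambda = Omega' Omega,

so Lambda is symmetric positive semidefinite by construction and is kept at
unit trace.  Training minimises the GLVQ cost

    sum_i phi(mu_i),   mu_i = (d_J - d_K) / (d_J + d_K),

where d_J is the distance of sample i to its own-class prototype and d_K
the distance to the other prototype; mu_i in [-1, 1] is negative for
correctly classified samples.  Both the prototypes and Omega are adapted by
batch gradient descent with analytic gradients.

The module follows the statsmodels convention: ``GMLVQ`` holds the data and
``fit()`` returns a ``GMLVQResults`` object carrying the estimates,
diagnostics, ``summary()``, and prediction methods.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables import CLASS_DECLINING, CLASS_STABLE, FEATURE_COLUMNS

__all__ = ["GMLVQ", "GMLVQResults", "metric_distance", "glvq_cost", "glvq_cost_gradients"]


def metric_distance(x: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Squared distance (x-w)' Lambda (x-w) under a PSD metric tensor."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if x.shape != w.shape or lam.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, w {w.shape}, lambda {lam.shape}"
        )
    diff = x - w
    return float(diff @ lam @ diff)


def _mu_terms(Z, y_idx, prototypes, omega, link="identity"):
    """Vectorized per-sample distances and mu for the 2-prototype case.

    Returns (mu, phi, phi_prime, dJ, dK, diffs, projs) where diffs[k] and
    projs[k] = Omega @ (x - w_k) are kept for gradient assembly.
    """
    diffs = Z[None, :, :] - prototypes[:, None, :]          # (2, n, d)
    projs = diffs @ omega.T                                  # (2, n, d)
    dists = np.einsum("knd,knd->kn", projs, projs)           # (2, n)
    n = Z.shape[0]
    rows = np.arange(n)
    dJ = dists[y_idx, rows]
    dK = dists[1 - y_idx, rows]
    S = dJ + dK
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(S > 0, (dJ - dK) / np.where(S > 0, S, 1.0), 0.0)
    if link == "identity":
        phi = mu
        phi_prime = np.ones_like(mu)
    elif link == "sigmoid":
        phi = 1.0 / (1.0 + np.exp(-mu))
        phi_prime = phi * (1.0 - phi)
    else:
        raise ValueError(f"unknown cost link {link!r}")
    return mu, phi, phi_prime, dJ, dK, S, diffs, projs


def glvq_cost(Z, y_idx, prototypes, omega, link="identity"):
    """GLVQ cost sum_i phi(mu_i) on standardized data.

    ``y_idx`` holds 0/1 indices into ``prototypes`` (the correct class per
    sample).  Samples at zero distance from both prototypes contribute
    mu = 0.
    """
    Z = np.asarray(Z, dtype=float)
    y_idx = np.asarray(y_idx, dtype=int)
    _, phi, *_ = _mu_terms(Z, y_idx, np.asarray(prototypes, float),
                           np.asarray(omega, float), link)
    return float(phi.sum())


def glvq_cost_gradients(Z, y_idx, prototypes, omega, link="identity"):
    """Analytic gradients of the GLVQ cost w.r.t. prototypes and Omega.

    d(cost)/d(dJ) = phi' * 2 dK / S^2 and d(cost)/d(dK) = -phi' * 2 dJ / S^2
    with S = dJ + dK; dd/dw = -2 Lambda (x - w) and
    dd/dOmega = 2 Omega (x - w)(x - w)'.
    """
    Z = np.asarray(Z, dtype=float)
    y_idx = np.asarray(y_idx, dtype=int)
    prototypes = np.asarray(prototypes, dtype=float)
    omega = np.asarray(omega, dtype=float)
    mu, _, phi_prime, dJ, dK, S, diffs, projs = _mu_terms(Z, y_idx, prototypes, omega, link)

    ok = S > 0
    S2 = np.where(ok, S * S, 1.0)
    gJ = np.where(ok, phi_prime * 2.0 * dK / S2, 0.0)   # d cost / d dJ
    gK = np.where(ok, phi_prime * -2.0 * dJ / S2, 0.0)  # d cost / d dK

    n = Z.shape[0]
    rows = np.arange(n)
    # per-sample weight attached to each of the two prototypes
    g_per_proto = np.zeros((2, n))
    g_per_proto[y_idx, rows] = gJ
    g_per_proto[1 - y_idx, rows] = gK

    lam = omega.T @ omega
    grad_w = np.einsum("kn,knd->kd", g_per_proto, diffs @ lam) * -2.0
    grad_omega = 2.0 * np.einsum("kn,knd,kne->de", g_per_proto, projs, diffs)
    return grad_w, grad_omega


class GMLVQ:
    """Two-class GMLVQ model specification.

    Parameters
    ----------
    X : array-like (n, d)
        Raw feature matrix (unstandardized; z-scoring happens in ``fit``).
    y : array-like of str
        Class label per sample; must take exactly the two values in
        ``class_names``.
    class_names : (str, str)
        Ordered pair; the first class anchors the scalar projection at 0,
        the second at 1.
    feature_names : sequence of str, optional
    """

    def __init__(self, X, y, class_names=(CLASS_STABLE, CLASS_DECLINING),
                 feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.class_names = tuple(class_names)
        if len(self.class_names) != 2:
            raise ValueError("exactly two classes supported")
        unknown = set(np.unique(y)) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
        counts = [(y == c).sum() for c in self.class_names]
        if min(counts) < 2:
            raise ValueError(
                f"need >=2 subjects per class, got {dict(zip(self.class_names, counts))}"
            )
        self.X = X
        self.y_idx = (y == self.class_names[1]).astype(int)
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features=FEATURE_COLUMNS,
                       label_col: str = "class_label",
                       class_names=(CLASS_STABLE, CLASS_DECLINING)) -> "GMLVQ":
        """Build from a cohort table, keeping only rows of the two classes."""
        sub = df[df[label_col].isin(class_names)]
        if not len(sub):
            raise ValueError(f"no rows with {label_col} in {class_names}")
        return cls(sub[list(features)].to_numpy(float), sub[label_col].to_numpy(),
                   class_names=class_names, feature_names=list(features))

    def fit(self, learning_rate_prototype: float = 0.05,
            learning_rate_omega: float = 0.005, epochs: int = 500,
            tolerance: float = 1e-7, seed: int = 0,
            cost_link: str = "identity", init: str = "mean") -> "GMLVQResults":
        """Train by batch gradient descent.

        Learning rates decay as 1/(1 + epoch/100); a step that increases
        the cost is rejected and retried at half step (the backtracking
        factor is kept, so accepted steps form a non-increasing cost
        sequence).  Lambda = Omega'Omega is renormalized to unit trace
        after every epoch; mu is invariant to that rescaling so the cost is
        unaffected.
        """
        if learning_rate_prototype <= 0 or learning_rate_omega <= 0:
            raise ValueError("learning rates must be positive")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")

        mean = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = [self.feature_names[j] for j in np.flatnonzero(sd <= 0)]
            raise ValueError(f"constant feature(s), cannot standardize: {bad}")
        Z = (self.X - mean) / sd

        d = Z.shape[1]
        centre = np.median if init == "median" else np.mean
        prototypes = np.stack([
            centre(Z[self.y_idx == k], axis=0) for k in (0, 1)
        ])
        if np.allclose(prototypes[0], prototypes[1]):
            # coincident class centres: jitter deterministically so the
            # prototype axis is defined
            rng = np.random.default_rng(seed)
            prototypes = prototypes + 1e-6 * rng.standard_normal(prototypes.shape)
        omega = np.eye(d) / np.sqrt(d)

        cost = glvq_cost(Z, self.y_idx, prototypes, omega, cost_link)
        backtrack = 1.0
        epochs_run = 0
        converged = False
        for epoch in range(epochs):
            decay = 1.0 / (1.0 + epoch / 100.0)
            grad_w, grad_omega = glvq_cost_gradients(
                Z, self.y_idx, prototypes, omega, cost_link)
            accepted = False
            for _ in range(30):
                step_w = learning_rate_prototype * decay * backtrack
                step_o = learning_rate_omega * decay * backtrack
                new_w = prototypes - step_w * grad_w
                new_omega = omega - step_o * grad_omega
                new_omega = new_omega / np.sqrt(np.trace(new_omega.T @ new_omega))
                new_cost = glvq_cost(Z, self.y_idx, new_w, new_omega, cost_link)
                if new_cost <= cost + 1e-12 * max(abs(cost), 1.0):
                    accepted = True
                    break
                backtrack *= 0.5
            epochs_run = epoch + 1
            if not accepted:
                converged = True
                break
            delta = abs(cost - new_cost) / max(abs(cost), 1e-12)
            prototypes, omega, cost = new_w, new_omega, new_cost
            if delta < tolerance:
                converged = True
                break

        lam = omega.T @ omega
        lam = lam / np.trace(lam)
        meta = {
            "epochs_run": epochs_run,
            "final_cost": float(cost),
            "converged": bool(converged),
            "learning_rate_prototype": learning_rate_prototype,
            "learning_rate_omega": learning_rate_omega,
            "tolerance": tolerance,
            "cost_link": cost_link,
            "init": init,
            "seed": int(seed),
        }
        return GMLVQResults(self.class_names, self.feature_names, prototypes,
                            omega, lam, mean, sd, meta)


class GMLVQResults:
    """Fitted GMLVQ model: prototypes, metric tensor, scaler and metadata.

    Prototypes are stored in standardized units; ``classify`` and
    ``scalar_projection`` accept raw-unit inputs and apply the training
    scaler internally.
    """

    def __init__(self, class_names, feature_names, prototypes, omega, lam,
                 scaler_mean, scaler_sd, meta):
        self.class_names = tuple(class_names)
        self.feature_names = list(feature_names)
        self.prototypes = np.asarray(prototypes, float)
        self.omega = np.asarray(omega, float)
        self.lambda_ = np.asarray(lam, float)
        self.scaler_mean = np.asarray(scaler_mean, float)
        self.scaler_sd = np.asarray(scaler_sd, float)
        self.meta = dict(meta)

    # -- prediction --------------------------------------------------------

    def standardize(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return (X - self.scaler_mean) / self.scaler_sd

    def prototype_raw(self, class_name: str) -> np.ndarray:
        """Prototype back-transformed to raw feature units."""
        k = self.class_names.index(class_name)
        return self.prototypes[k] * self.scaler_sd + self.scaler_mean

    def classify(self, X) -> np.ndarray:
        """Nearest-prototype label under the learnt metric, raw-unit input."""
        Z = self.standardize(X)
        diffs = Z[None, :, :] - self.prototypes[:, None, :]
        dists = np.einsum("knd,de,kne->kn", diffs, self.lambda_, diffs)
        return np.asarray(self.class_names)[np.argmin(dists, axis=0)]

    def scalar_projection(self, X) -> np.ndarray:
        """Prognostic index s for raw-unit input; see :mod:`tautraj.index`."""
        from .index import scalar_projection
        return scalar_projection(X, self)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = ["GMLVQ Results", "=" * 60]
        lines.append(f"classes: {self.class_names[0]} vs {self.class_names[1]}")
        lines.append(f"epochs run: {self.meta['epochs_run']}  "
                     f"converged: {self.meta['converged']}  "
                     f"final cost: {self.meta['final_cost']:.6g}")
        lines.append("")
        lines.append("prototypes (standardized units):")
        header = "  {:<22s}" + "".join(
            " {:>14s}".format(f) for f in self.feature_names)
        lines.append(header.format("class"))
        for k, name in enumerate(self.class_names):
            lines.append("  {:<22s}".format(name) + "".join(
                " {:>14.4f}".format(v) for v in self.prototypes[k]))
        lines.append("")
        lines.append("metric tensor Lambda (unit trace; diagonal = feature relevances):")
        for j, f in enumerate(self.feature_names):
            lines.append("  {:<22s}".format(f) + "".join(
                " {:>14.4f}".format(v) for v in self.lambda_[j]))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "tautraj-gmlvq-1",
            "class_names": list(self.class_names),
            "feature_names": self.feature_names,
            "prototypes": self.prototypes.tolist(),
            "omega": self.omega.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "meta": self.meta,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "GMLVQResults":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("format") != "tautraj-gmlvq-1":
            raise ValueError(f"unrecognized model file: {path}")
        omega = np.asarray(payload["omega"], float)
        lam = omega.T @ omega
        lam = lam / np.trace(lam)
        return cls(payload["class_names"], payload["feature_names"],
                   payload["prototypes"], omega, lam,
                   payload["scaler_mean"], payload["scaler_sd"], payload["meta"])
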