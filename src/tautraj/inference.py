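"""Group-level inference on tau-accumulation rates and stratification labels.

Implements the study's group statistics:

* per-ROI one-sample right-tailed t-tests of the annualized tau rate
  against 0 (which regions accumulate tau in a stratum; uncorrected
  p < 0.05 by design),
* a two-sample t-test across the 36 per-ROI mean rates comparing two
  strata ("global" accumulation; ROI means are the observations, giving
  df = 2*36 - 2 = 70),
* per-Braak-stage baseline SUVR contrasts between strata,
* a one-way random-effects single-measure ICC between two groups' per-ROI
  mean-rate vectors (regional specificity; near 0 means the strata
  accumulate in different regions),
* Cohen's kappa for agreement between stratification and baseline
  syndromic diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "regional_accumulation_tests", "global_rate_test",
    "braak_baseline_contrast", "ICCResult", "icc_one_way",
    "KappaResult", "cohens_kappa",
]


def regional_accumulation_tests(rate_table: pd.DataFrame, subjects,
                                rois=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI one-sample right-tailed t of rate > 0 within a subject group.

    No multiplicity correction is applied (the study reports uncorrected
    p < 0.05).  Zero-variance ROIs get NaN statistics and are flagged
    non-significant.
    """
    sub = rate_table[rate_table["subject_id"].isin(set(subjects))]
    sub = sub[sub["measure"] != "PACC"]
    if rois is not None:
        sub = sub[sub["measure"].isin(rois)]
    rows = []
    for roi, grp in sub.groupby("measure", sort=False):
        r = grp["rate"].to_numpy(float)
        n = len(r)
        if n < 2:
            raise ValueError(f"ROI {roi}: need >=2 subjects, got {n}")
        if np.allclose(r, r[0]):
            t = p = np.nan
        else:
            t, p = stats.ttest_1samp(r, 0.0, alternative="greater")
        rows.append({"roi": roi, "n": n, "mean_rate": r.mean(),
                     "t": t, "df": n - 1, "p": p,
                     "significant": bool(p < alpha) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


def global_rate_test(mean_rates_a, mean_rates_b, equal_var: bool = True) -> dict:
    """Two-sample t across per-ROI mean rates for two strata.

    The two vectors of per-ROI group means are treated as the observations
    (pooled-variance t; with 36 ROIs per group df = 70).  The ratio of
    grand means (A / B) is reported alongside.
    """
    a = np.asarray(mean_rates_a, dtype=float)
    b = np.asarray(mean_rates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched ROI sets")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else None
    ratio = float(a.mean() / b.mean()) if b.mean() != 0 else np.inf
    return {"t": float(t), "df": df, "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "ratio": ratio}


def braak_baseline_contrast(baseline: pd.DataFrame, braak_map: dict,
                            group_a, group_b) -> pd.DataFrame:
    """Per-Braak-stage baseline SUVR contrast between two subject groups.

    The per-subject stage composite is the unweighted mean of the member
    ROIs' baseline SUVRs; groups are compared with a pooled two-sample t
    (df = n_a + n_b - 2).
    """
    stages = sorted(set(braak_map.values()))
    missing = [r for r in baseline.columns
               if r != "PACC" and r not in braak_map]
    if missing:
        raise ValueError(f"ROIs not in Braak map: {missing}")
    rows = []
    for stage in stages:
        rois = [r for r, s in braak_map.items() if s == stage and r in baseline.columns]
        if not rois:
            raise ValueError(f"Braak stage {stage} has no ROIs in the data")
        composite = baseline[rois].mean(axis=1)
        ca = composite.loc[composite.index.isin(set(group_a))].to_numpy(float)
        cb = composite.loc[composite.index.isin(set(group_b))].to_numpy(float)
        t, p = stats.ttest_ind(ca, cb, equal_var=True)
        rows.append({"stage": stage, "n_rois": len(rois),
                     "mean_diff": float(ca.mean() - cb.mean()),
                     "t": float(t), "df": len(ca) + len(cb) - 2, "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class ICCResult:
    """One-way random-effects, single-measure ICC for k = 2 raters."""

    icc: float
    ci_low: float
    ci_high: float
    F: float
    df1: int
    df2: int
    p: float

    def summary(self) -> str:
        return (f"ICC(1) = {self.icc:.3f} [{self.ci_low:.3f} {self.ci_high:.3f}], "
                f"F({self.df1},{self.df2}) = {self.F:.3f}, p = {self.p:.3g}")


def icc_one_way(vector_a, vector_b, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects single-measure ICC between two vectors.

    Targets are the n paired entries (e.g. ROIs), raters k = 2:
    ICC = (MSB - MSW)/(MSB + (k-1) MSW); F = MSB/MSW with df (n-1, n(k-1));
    the CI comes from F quantiles.
    """
    a = np.asarray(vector_a, dtype=float)
    b = np.asarray(vector_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 targets for the ICC")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite input")
    k = 2
    data = np.column_stack([a, b])
    target_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((target_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - target_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0 and msb == 0:
        raise ValueError("zero variance in both directions; ICC undefined")
    df1, df2 = n - 1, n * (k - 1)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    if msw > 0:
        F = msb / msw
        fl = F / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = F * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (fl - 1) / (fl + k - 1)
        ci_high = (fu - 1) / (fu + k - 1)
        p = float(stats.f.sf(F, df1, df2))
    else:  # perfect within-target agreement
        F, ci_low, ci_high, p = np.inf, 1.0, 1.0, 0.0
    return ICCResult(float(icc), float(ci_low), float(ci_high), float(F),
                     df1, df2, p)


@dataclass
class KappaResult:
    """Cohen's kappa with asymptotic (large-sample) standard-error CI."""

    kappa: float
    ci_low: float
    ci_high: float
    p: float
    po: float
    pe: float

    def summary(self) -> str:
        return (f"kappa = {self.kappa:.3f} [{self.ci_low:.4f}, {self.ci_high:.4f}], "
                f"p = {self.p:.3g} (Po = {self.po:.3f}, Pe = {self.pe:.3f})")


def cohens_kappa(table, alpha: float = 0.05) -> KappaResult:
    """Cohen's kappa from a square contingency table of counts.

    Po is the observed agreement (diagonal fraction), Pe the chance
    agreement from the marginal products, kappa = (Po - Pe)/(1 - Pe).  The
    CI uses the asymptotic SE of kappa-hat; the p-value tests kappa = 0
    with the null-hypothesis SE.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(T < 0) or not np.all(T == np.round(T)):
        raise ValueError("counts must be nonnegative integers")
    n = T.sum()
    if n <= 0:
        raise ValueError("empty table")
    P = T / n
    po = float(np.trace(P))
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: Pe = 1, kappa undefined")
    kappa = (po - pe) / (1 - pe)

    # Fleiss-Cohen-Everitt asymptotic variance of kappa-hat
    diag = np.diag(P)
    a = np.sum(diag * (1 - (row + col) * (1 - kappa)) ** 2)
    b = (1 - kappa) ** 2 * sum(
        P[i, j] * (col[i] + row[j]) ** 2
        for i in range(len(row)) for j in range(len(col)) if i != j
    )
    c = (kappa - pe * (1 - kappa)) ** 2
    var = (a + b - c) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))

    # null SE (kappa = 0) for the significance test
    var0 = (pe + pe ** 2 - np.sum(row * col * (row + col))) / (n * (1 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * float(stats.norm.sf(abs(kappa) / se0)) if se0 > 0 else np.nan
    return KappaResult(float(kappa), float(kappa - z * se), float(kappa + z * se),
                       p, po, pe)
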