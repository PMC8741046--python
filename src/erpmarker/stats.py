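"""Evaluation statistics: ROC/AUC with Hanley-McNeil confidence intervals and
a sensitivity-maximizing cutoff rule, Mann-Whitney U with the continuity- and
tie-corrected normal approximation, Pearson correlation with Student-t p-value
and Fisher-z confidence interval, 2x2 chi-square, Bonferroni adjustment, and
a gender-balanced ROC resampling check.

Two-tailed p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class StatResult:
    name: str
    statistic: float
    p: float
    ci95: tuple[float, float] | None = None
    n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    above_chance: bool = True  # False when no threshold had specificity > 0.5


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float] | None = None
    operating_point: OperatingPoint | None = None
    n_pos: int = 0
    n_neg: int = 0


def roc_auc(scores, labels) -> RocResult:
    """Empirical ROC over all distinct score thresholds (positive class = 1).

    The AUC equals the Mann-Whitney probability that a positive outscores a
    negative, with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    roc = RocResult(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr,
                    auc=auc, n_pos=n_pos, n_neg=n_neg)
    if 0.0 < auc < 1.0 and n_pos >= 2 and n_neg >= 2:
        roc.ci95 = auc_ci_hanley(auc, n_pos, n_neg)
    roc.operating_point = select_cutoff(roc)
    return roc


def auc_ci_hanley(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Hanley-McNeil 95% confidence interval for an empirical AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg),
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the interval A +- 1.96 SE is
    clipped to [0, 1].
    """
    if not 0.0 < auc < 1.0:
        raise ValueError("Hanley-McNeil CI requires 0 < AUC < 1")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("Hanley-McNeil CI requires >= 2 per class")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    se = np.sqrt((auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc ** 2)
                  + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg))
    return (float(max(0.0, auc - Z95 * se)), float(min(1.0, auc + Z95 * se)))


def select_cutoff(roc: RocResult) -> OperatingPoint:
    """The cutoff maximizing sensitivity subject to specificity > 0.5.

    Ties are broken by higher specificity, then by lower threshold. If no
    threshold achieves above-chance specificity, the best-specificity point
    is returned flagged.
    """
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    admissible = spec > 0.5
    if not admissible.any():
        i = int(np.lexsort((thr, -sens, -spec))[0])
        return OperatingPoint(float(thr[i]), float(sens[i]), float(spec[i]),
                              above_chance=False)
    idx = np.flatnonzero(admissible)
    order = np.lexsort((thr[idx], -spec[idx], -sens[idx]))
    i = int(idx[order[0]])
    return OperatingPoint(float(thr[i]), float(sens[i]), float(spec[i]))


def mann_whitney_z_from_u(u: float, m: int, n: int,
                          tie_term: float = 0.0) -> tuple[float, float]:
    """Continuity-corrected normal approximation: Z and two-tailed p from U.

    mu_U = mn/2; sigma_U^2 = mn(m+n+1)/12 minus the mid-rank tie correction;
    U is shifted 0.5 toward the mean before standardizing.
    """
    mu = m * n / 2.0
    nn = m + n
    var = m * n * (nn + 1) / 12.0 - tie_term
    if var <= 0:
        return 0.0, 1.0
    cc = 0.5 * np.sign(mu - u)
    z = (u + cc - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return float(z), p


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U test with the continuity-corrected normal approximation.

    U is the statistic of the first sample (ties mid-ranked); the variance
    carries the standard tie correction when ties exist.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u_x = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    nn = m + n
    _, counts = np.unique(combined, return_counts=True)
    tie_term = m * n * float(((counts ** 3 - counts).sum())) / (12.0 * nn * (nn - 1))
    z, p = mann_whitney_z_from_u(u_x, m, n, tie_term)
    return StatResult("mann_whitney", statistic=u_x, p=p, n=(m, n),
                      extra={"z": z, "u": u_x})


def fisher_ci(r: float, n: int) -> tuple[float, float]:
    """95% Fisher-z confidence interval: tanh(atanh(r) +- 1.96 / sqrt(n-3))."""
    if n < 4:
        raise ValueError("Fisher-z CI requires n >= 4")
    rc = float(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15))
    z = np.arctanh(rc)
    half = Z95 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_with_ci(x, y) -> StatResult:
    """Pearson r with two-tailed Student-t p (n-2 df) and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Pearson correlation requires n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a correlation input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
    return StatResult("pearson", statistic=r, p=p, ci95=fisher_ci(r, n), n=(n,))


def chi_square_2x2(table, correction: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 count table (1 df, two-tailed).

    Uncorrected by default; Yates continuity correction behind the flag.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return StatResult("chi_square", statistic=float(chi2), p=float(p),
                      n=(int(arr.sum()),))


def bonferroni(p_values, k: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * k), with k >= len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if k < len(p):
        raise ValueError("k must be at least the number of p-values")
    return np.minimum(1.0, p * k)


def gender_balanced_roc(
    scores, labels, sex, n_females: int = 3, n_iter: int = 5, seed: int = 0
) -> dict:
    """ROC analysis under gender-balanced control subsampling.

    Each iteration keeps all patients (label 1) and all male controls, plus
    `n_females` female controls drawn without repetition across iterations
    (so n_iter * n_females may not exceed the female-control count). Reports
    the mean and min-max range of the AUC plus per-iteration operating points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    sex = np.asarray(sex)
    ctrl_f = np.flatnonzero((labels == 0) & (sex == "F"))
    keep_always = np.flatnonzero((labels == 1) | ((labels == 0) & (sex == "M")))
    if n_iter * n_females > len(ctrl_f):
        raise ValueError(
            f"need {n_iter * n_females} female controls for disjoint draws, "
            f"have {len(ctrl_f)}")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(ctrl_f)
    aucs, points = [], []
    for i in range(n_iter):
        chosen = pool[i * n_females:(i + 1) * n_females]
        idx = np.concatenate([keep_always, chosen])
        roc = roc_auc(scores[idx], labels[idx])
        aucs.append(roc.auc)
        points.append(roc.operating_point)
    return {
        "mean_auc": float(np.mean(aucs)),
        "auc_range": (float(np.min(aucs)), float(np.max(aucs))),
        "aucs": [float(a) for a in aucs],
        "operating_points": points,
    }
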