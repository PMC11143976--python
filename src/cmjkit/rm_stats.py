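"""One-way repeated-measures ANOVA with sphericity handling.

Implements the within-subject decomposition for a complete participants x
conditions matrix: F = MS_conditions / MS_error with df (k-1, (k-1)(n-1)),
Mauchly's sphericity test, the Greenhouse-Geisser epsilon correction, partial
eta-squared effect sizes with the 0.04 / 0.25 / 0.64 classification
thresholds, and Bonferroni-adjusted paired post hoc t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "AnovaResult",
    "rm_anova",
    "gg_epsilon",
    "mauchly_test",
    "bonferroni_posthoc",
    "classify_effect_size",
]

#: Partial eta-squared thresholds: small, moderate, large.
EFFECT_THRESHOLDS = (0.04, 0.25, 0.64)


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_effect: float  # possibly epsilon-corrected
    df_error: float
    p_value: float
    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    partial_eta_sq: float
    effect_label: str
    sphericity_corrected: bool


def _validate(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete n x k matrix with n >= 2, k >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing/non-finite cells")
    return m


def _contrast_covariance(m: np.ndarray) -> np.ndarray:
    """Covariance of the data projected onto k-1 orthonormal contrasts."""
    k = m.shape[1]
    # Helmert-style orthonormal basis of the space orthogonal to the mean
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    proj = m @ c
    return np.cov(proj, rowvar=False, ddof=1)


def gg_epsilon(m: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of conditions.

    epsilon = tr(S_c)^2 / ((k-1) * tr(S_c^2)) for the contrast-projected
    covariance S_c; bounded in [1/(k-1), 1].
    """
    m = _validate(m)
    k = m.shape[1]
    if k == 2:
        return 1.0
    s = _contrast_covariance(m)
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0:
        raise DegenerateDataError("zero-variance matrix: epsilon undefined")
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(m: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test.

    W = det(S_c) / (tr(S_c)/(k-1))^(k-1); the chi-square approximation uses
    -(n-1) f ln W on k(k-1)/2 - 1 degrees of freedom.  For k = 2 the test is
    degenerate: returns (1.0, 1.0).
    """
    m = _validate(m)
    n, k = m.shape
    if k == 2:
        return 1.0, 1.0
    s = _contrast_covariance(m)
    sign, logdet = np.linalg.slogdet(s)
    tr = np.trace(s)
    if sign <= 0 or tr <= 0:
        # singular covariance (e.g. n - 1 < k - 1): sphericity untestable
        return 0.0, float("nan")
    d = k - 1
    log_w = logdet - d * np.log(tr / d)
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * log_w
    df = k * (k - 1) // 2 - 1
    # second-order term of the chi-square approximation (as in ezANOVA)
    w2 = (
        (d + 2)
        * (d - 1)
        * (d - 2)
        * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return float(np.exp(log_w)), p


def rm_anova(
    m: np.ndarray,
    *,
    sphericity_alpha: float = 0.05,
    force_correction: bool | None = None,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on an n x k condition matrix.

    Sums of squares partition the within-subject variation:
    SS_total = SS_subjects + SS_conditions + SS_error.  When Mauchly's test
    rejects at ``sphericity_alpha`` (or ``force_correction=True``), the
    Greenhouse-Geisser epsilon multiplies both degrees of freedom before the
    p-value is computed.  Partial eta-squared is
    SS_conditions / (SS_conditions + SS_error).
    """
    m = _validate(m)
    n, k = m.shape
    grand = m.mean()
    subj_means = m.mean(axis=1)
    cond_means = m.mean(axis=0)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        if ms_cond <= 0:
            raise DegenerateDataError("zero-variance matrix: F undefined")
        ms_err = np.finfo(float).tiny
    f_stat = ms_cond / ms_err

    w, w_p = mauchly_test(m) if k >= 3 else (1.0, 1.0)
    eps = gg_epsilon(m) if k >= 3 else 1.0
    if force_correction is None:
        corrected = k >= 3 and np.isfinite(w_p) and w_p < sphericity_alpha
    else:
        corrected = bool(force_correction) and k >= 3
    e = eps if corrected else 1.0
    p = float(stats.f.sf(f_stat, e * df_cond, e * df_err))

    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_effect=e * df_cond,
        df_error=e * df_err,
        p_value=p,
        mauchly_w=w,
        mauchly_p=w_p,
        gg_epsilon=eps,
        partial_eta_sq=float(eta),
        effect_label=classify_effect_size(eta),
        sphericity_corrected=corrected,
    )


def bonferroni_posthoc(
    m: np.ndarray, labels: list[str] | None = None, *, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni adjustment.

    Adjusted p = min(1, raw p * number of pairs); ``significant`` flags
    adjusted p < alpha.
    """
    m = _validate(m)
    k = m.shape[1]
    labels = labels or [f"c{j}" for j in range(k)]
    pairs = list(combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        t, p = stats.ttest_rel(m[:, i], m[:, j])
        if np.isnan(p):  # zero difference variance: no evidence either way
            t, p = 0.0, 1.0
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append(
            {
                "condition_a": labels[i],
                "condition_b": labels[j],
                "mean_diff": float(np.mean(m[:, i] - m[:, j])),
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def classify_effect_size(eta_sq: float) -> str:
    """Classify partial eta-squared: <0.04 negligible, [0.04, 0.25) small,
    [0.25, 0.64) moderate, >=0.64 large (boundaries inclusive upward)."""
    small, moderate, large = EFFECT_THRESHOLDS
    if eta_sq >= large:
        return "large"
    if eta_sq >= moderate:
        return "moderate"
    if eta_sq >= small:
        return "small"
    return "negligible"
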