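"""1D statistical parametric mapping (SPM) for normalized jump curves.

A paired t-statistic is computed at every node of the normalized-time axis,
giving a t-field T(q) with n-1 degrees of freedom.  Because adjacent nodes
are correlated, the familywise alpha=0.05 threshold t* is set with random
field theory (RFT): the smoothness of the residual fields is estimated as a
FWHM (full width at half maximum, in nodes) from their normalized gradients,
the field length is expressed in resels (Q / FWHM), and t* solves

    P(max |T| > t*) ~= S_t(t*) + R * (sqrt(4 ln 2) / 2 pi) *
                       (1 + t*^2 / nu)^(-(nu - 1)/2) = alpha

(the two-term Euler-characteristic expansion for a 1D t-field of nu degrees
of freedom and R resels; S_t is the t survival function, and the two-tailed
test splits alpha between the tails).  Supra-threshold clusters are maximal
runs with |T| > t*; their endpoints are refined by linear interpolation and
a cluster-level p-value is assigned from the RFT Poisson-clumping
approximation given the cluster extent in resels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, pi, sqrt

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "SpmCluster",
    "SpmResult",
    "paired_t_curve",
    "estimate_fwhm",
    "rft_threshold",
    "expected_clusters",
    "find_clusters",
    "spm_paired_test",
]

_SQRT_4LN2 = sqrt(4.0 * log(2.0))


@dataclass(frozen=True)
class SpmCluster:
    """One supra-threshold cluster of the t-field."""

    start_percent: float  # interpolated crossing, % of normalized time
    end_percent: float
    extent_resels: float
    p_value: float
    sign: int  # +1 above +t*, -1 below -t*

    @property
    def extent_percent(self) -> float:
        return self.end_percent - self.start_percent


@dataclass
class SpmResult:
    t_curve: np.ndarray  # Q+1 nodes; NaN at masked nodes
    df: float  # n - 1
    fwhm: float  # nodes
    resel_count: float
    t_star: float
    clusters: list[SpmCluster]
    alpha: float
    two_tailed: bool
    mask: np.ndarray = field(default_factory=lambda: np.array([], bool))

    @property
    def significant(self) -> bool:
        return bool(self.clusters)


def paired_t_curve(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Node-wise paired t-statistic between two (n_participants, Q+1) arrays.

    Returns ``(t_curve, residuals, mask)`` where residuals are the
    participant difference fields minus their node-wise mean (input to
    :func:`estimate_fwhm`) and ``mask`` flags nodes with zero difference
    variance, where t is undefined (t is NaN there).
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape != b.shape:
        raise ValueError("paired designs need identical shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t needs n >= 2 participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    mask = sd <= 0
    t = np.full(d.shape[1], np.nan)
    np.divide(mean, sd / sqrt(n), out=t, where=~mask)
    residuals = d - mean
    return t, residuals, mask


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, in nodes) of a set of residual fields.

    Gradient-based estimator for 1D Gaussian fields: with residuals
    variance-normalized node-wise, FWHM = sqrt(4 ln 2) / RMS gradient;
    the per-node resel densities are averaged and inverted.
    """
    r = np.atleast_2d(np.asarray(residuals, float))
    ssq = (r**2).sum(axis=0)
    good = ssq > 0
    if not np.any(good):
        raise ValueError("all-zero residuals: smoothness undefined")
    # gradients of the unit-variance-normalized field
    r_norm = r[:, good] / np.sqrt(ssq[good])
    grad = np.gradient(r_norm, axis=1)
    v = (grad**2).sum(axis=0)
    resels_per_node = np.sqrt(v / (4.0 * log(2.0)))
    mean_rpn = resels_per_node.mean()
    if mean_rpn <= 0:
        return float("inf")
    return float(1.0 / mean_rpn)


def _ec_density_1d(u: float, df: float) -> float:
    """EC density of a 1D t-field (expected upcrossings per resel)."""
    return _SQRT_4LN2 / (2.0 * pi) * (1.0 + u**2 / df) ** (-(df - 1.0) / 2.0)


def _max_exceedance_prob(u: float, df: float, resels: float) -> float:
    """P(max T > u) for a one-tailed 1D t-field: EC expectation, capped at 1."""
    p = stats.t.sf(u, df) + resels * _ec_density_1d(u, df)
    return min(1.0, p)


def rft_threshold(
    df: float, resel_count: float, alpha: float = 0.05, two_tailed: bool = True
) -> float:
    """Critical threshold t* with familywise P(max |T| > t*) = alpha.

    In the resel_count -> 0 limit this reduces to the ordinary (uncorrected)
    t quantile.  Monotone root finding on the EC expansion.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    if resel_count < 0:
        raise ValueError("resel_count must be >= 0")
    a = alpha / 2.0 if two_tailed else alpha

    def fn(u: float) -> float:
        return _max_exceedance_prob(u, df, resel_count) - a

    lo = float(stats.t.isf(a, df))  # uncorrected quantile: fn(lo) >= 0
    if fn(lo) <= 0:  # zero resels: the EC expansion reduces to the point term
        return lo
    hi = lo + 1.0
    while fn(hi) > 0:
        hi += 2.0
        if hi > 1e3:
            raise RuntimeError("RFT threshold search failed to bracket")
    return float(optimize.brentq(fn, lo, hi, xtol=1e-10))


def expected_clusters(u: float, df: float, resels: float) -> float:
    """Expected number of supra-threshold clusters at height u (one tail)."""
    return resels * _ec_density_1d(u, df) + stats.t.sf(u, df)


def _cluster_p(
    extent_resels: float, u: float, df: float, resels: float, two_tailed: bool
) -> float:
    """Cluster-level p-value via the Poisson clumping heuristic.

    Expected cluster count E[m] and expected supra-threshold volume E[n]
    (both in resels) give the extent distribution P(ext >= k) =
    exp(-beta k^2) with beta = (Gamma(3/2) E[m] / E[n])^2 for a 1D field;
    p = 1 - exp(-E[m] * P(ext >= k)).
    """
    em = expected_clusters(u, df, resels)
    en = resels * stats.t.sf(u, df)
    if two_tailed:
        em *= 2.0
        en *= 2.0
    if em <= 0 or en <= 0:
        return 1.0
    beta = (special.gamma(1.5) * em / en) ** 2
    p_ext = np.exp(-beta * extent_resels**2)
    return float(min(1.0, -np.expm1(-em * p_ext)))


def find_clusters(
    t_curve: np.ndarray,
    t_star: float,
    fwhm: float,
    df: float,
    *,
    two_tailed: bool = True,
    alpha: float = 0.05,
) -> list[SpmCluster]:
    """Maximal contiguous supra-threshold runs with interpolated endpoints.

    Endpoints are reported as fractional percent of normalized time (linear
    interpolation of |t| across the threshold); extent is measured in resels
    (nodes / FWHM).  Masked (NaN) nodes never belong to a cluster.
    """
    t = np.asarray(t_curve, float)
    q = t.size - 1
    resels = q / fwhm if np.isfinite(fwhm) and fwhm > 0 else 0.0
    mag = np.abs(t)
    above = np.where(np.isnan(mag), False, mag > t_star)
    clusters: list[SpmCluster] = []
    i = 0
    while i <= q:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 <= q and above[j + 1]:
            j += 1
        # interpolate the crossings on each side when neighbours are finite
        start = float(i)
        if i > 0 and np.isfinite(mag[i - 1]):
            frac = (t_star - mag[i - 1]) / (mag[i] - mag[i - 1])
            start = (i - 1) + frac
        end = float(j)
        if j < q and np.isfinite(mag[j + 1]):
            frac = (mag[j] - t_star) / (mag[j] - mag[j + 1])
            end = j + frac
        extent_nodes = max(end - start, 1e-9)
        extent_resels = extent_nodes / fwhm if fwhm > 0 else 0.0
        sign = 1 if t[i + int(np.argmax(mag[i : j + 1]))] > 0 else -1
        clusters.append(
            SpmCluster(
                start_percent=round(start / q * 100.0, 1),
                end_percent=round(end / q * 100.0, 1),
                extent_resels=extent_resels,
                p_value=_cluster_p(extent_resels, t_star, df, resels, two_tailed),
                sign=sign,
            )
        )
        i = j + 1
    return clusters


def spm_paired_test(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    *,
    two_tailed: bool = True,
) -> SpmResult:
    """Full paired SPM: t-field, smoothness, RFT threshold, clusters.

    ``a`` and ``b`` are (n_participants, Q+1) arrays of normalized curves for
    the two conditions, rows paired by participant.  Deterministic given
    inputs.
    """
    t, residuals, mask = paired_t_curve(a, b)
    n = a.shape[0]
    df = n - 1
    fwhm = estimate_fwhm(residuals[:, ~mask] if mask.any() else residuals)
    q_eff = int((~mask).sum()) - 1  # masked nodes excluded from resel count
    resels = q_eff / fwhm if fwhm > 0 and np.isfinite(fwhm) else 0.0
    t_star = rft_threshold(df, resels, alpha, two_tailed)
    clusters = find_clusters(
        t, t_star, fwhm, df, two_tailed=two_tailed, alpha=alpha
    )
    return SpmResult(
        t_curve=t,
        df=float(df),
        fwhm=fwhm,
        resel_count=resels,
        t_star=t_star,
        clusters=clusters,
        alpha=alpha,
        two_tailed=two_tailed,
        mask=mask,
    )
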