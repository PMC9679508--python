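"""One-dimensional statistical parametric mapping over the stride cycle.

Stride curves (101 nodes) are aggregated to one median stride per subject
and condition; the two conditions are compared with a node-wise paired
t-test, giving a 101-node t-field.  Family-wise inference over the field
uses the expected Euler characteristic of a smooth 1D t-field: the field's
effective smoothness (FWHM, in nodes) is estimated from the normalized
residuals, the search region spans (101 - 1)/FWHM resels, and the critical
threshold t* solves

    alpha_eff = P(T > t*) + (resels) * sqrt(4 ln 2) / (2 pi)
                * (1 + t*^2 / nu) ^ (-(nu - 1)/2)

per tail, with alpha_eff = alpha / (2 m) for two-tailed, Bonferroni-
corrected inference over m variables.  Suprathreshold clusters are maximal
runs with |t| > t*, endpoints linearly interpolated to fractional % stride;
cluster p-values use the expected-cluster-extent approximation.  An
exhaustive sign-flip permutation of the paired differences provides an
independent threshold for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DegenerateFieldError, PairingError

N_NODES = 101


@dataclass
class SubjectStrideField:
    """Median-across-strides 101-node curve for one subject and condition."""

    subject_id: str
    condition: str
    variable: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_NODES,):
            raise ConfigurationError("stride field must have exactly 101 nodes")


@dataclass
class SPMResult:
    """A paired t-field with its RFT threshold and suprathreshold clusters."""

    t_field: np.ndarray
    df: int
    fwhm: float
    critical_threshold: float
    clusters: list = field(default_factory=list)  # {start_pct, end_pct, p}
    alpha: float = 0.05
    m_bonferroni: int = 1

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def median_stride_field(strides, subject_id: str, condition: str,
                        variable: str) -> SubjectStrideField:
    """Node-wise median over an iterable of valid 101-node stride vectors."""
    arr = np.asarray([np.asarray(s, dtype=float) for s in strides])
    if arr.ndim != 2 or arr.shape[1] != N_NODES:
        raise ConfigurationError("strides must be (n, 101)")
    return SubjectStrideField(subject_id, condition, variable,
                              np.median(arr, axis=0))


def _paired_differences(A, B):
    A = {f.subject_id: f for f in A}
    B = {f.subject_id: f for f in B}
    if set(A) != set(B):
        raise PairingError(f"subject mismatch: {sorted(A)} vs {sorted(B)}")
    subjects = sorted(A)
    if len(subjects) < 3:
        raise PairingError("need at least 3 paired subjects")
    return np.asarray([A[s].values - B[s].values for s in subjects])


def paired_t_field(A, B):
    """Node-wise paired t on per-subject differences.

    Returns ``(t_field, residuals, df)`` where the residuals are the
    mean-centred differences used for smoothness estimation.  Nodes with
    zero variance and zero mean give t = 0; zero variance with nonzero
    mean is degenerate and raises.
    """
    d = _paired_differences(A, B)
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero & (np.abs(mean) > 1e-12)):
        raise DegenerateFieldError("zero variance with nonzero mean difference")
    t = np.zeros(N_NODES)
    nz = ~zero
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    residuals = d - mean
    return t, residuals, n - 1


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, node units) from normalized residual gradients.

    Kiebel-style estimator: with residual fields r_i(x) normalized by the
    node-wise residual sum of squares, the per-node resel density is
    sqrt(sum_i (du_i/dx)^2 / (4 ln 2)); FWHM is the reciprocal of its
    mean.  Constant residuals (no gradient anywhere) return ``inf``, the
    sentinel meaning "use the pointwise t threshold".
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ConfigurationError("need >= 2 residual fields")
    ssq = (R ** 2).sum(axis=0)
    dR = np.diff(R, axis=1)
    v = (dR ** 2).sum(axis=0)
    denom = np.sqrt(ssq[:-1] * ssq[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        v = v / denom
    v = v[np.isfinite(v)]
    if v.size == 0 or v.mean() == 0:
        return np.inf
    resels_per_node = np.sqrt(v / (4 * np.log(2)))
    m = resels_per_node.mean()
    return np.inf if m == 0 else 1.0 / m


def _ec_density_1d(t: float, df: int) -> float:
    """1D Euler-characteristic density of a t-field (per resel)."""
    return (np.sqrt(4 * np.log(2)) / (2 * np.pi)
            * (1 + t ** 2 / df) ** (-(df - 1) / 2.0))


def expected_ec(t: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of the excursion set above ``t``."""
    return stats.t.sf(t, df) + resels * _ec_density_1d(t, df)


def rft_threshold(df: int, fwhm: float, n_nodes: int = N_NODES,
                  alpha: float = 0.05, two_tailed: bool = True,
                  m_comparisons: int = 1) -> float:
    """Critical t for family-wise inference over a smooth 1D t-field.

    Solves expected_EC(t*) = alpha_eff with alpha_eff = alpha/(2m) per tail
    for two-tailed Bonferroni-corrected inference (alpha/m one-tailed).
    ``fwhm = inf`` (constant residuals) degrades to the pointwise t
    quantile.  Monotone: non-increasing in fwhm and df, non-decreasing in
    m_comparisons.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must be in (0, 1)")
    if df < 1 or m_comparisons < 1:
        raise ConfigurationError("df and m_comparisons must be >= 1")
    a_eff = alpha / m_comparisons
    if two_tailed:
        a_eff /= 2.0
    if not np.isfinite(fwhm):
        return float(stats.t.isf(a_eff, df))
    if fwhm <= 0:
        raise ConfigurationError("fwhm must be positive")
    resels = (n_nodes - 1) / fwhm
    f = lambda t: expected_ec(t, df, resels) - a_eff
    lo, hi = 1e-3, 1e3
    if f(lo) < 0:  # already below alpha at ~0 (huge alpha); threshold ~ 0
        return lo
    if f(hi) > 0:
        # heavy t tails (tiny df) with many resels: the expected EC never
        # drops below alpha_eff, so no finite threshold controls the FWE
        return np.inf
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def suprathreshold_clusters(t_field: np.ndarray, critical_t: float,
                            df: int = 1, fwhm: float = np.inf,
                            alpha: float = 0.05) -> list:
    """Maximal runs of |t| above the threshold, as % stride with p-values.

    Endpoints are linearly interpolated between the straddling nodes to
    fractional % stride (node i maps to i% of the stride).  Cluster
    p-values use the RFT expected-cluster-extent approximation (exponential
    extents under Poisson clumping), capped at ``alpha``; with infinite
    smoothness the cap itself is reported.  The cluster set is invariant
    under sign flip of the whole field.
    """
    a = np.abs(np.asarray(t_field, dtype=float))
    if not np.isfinite(critical_t):
        return []
    above = a > critical_t
    if not above.any():
        return []
    clusters = []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d > 0) + 1)
    stops = list(np.flatnonzero(d < 0) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(a))
    for s, e in zip(starts, stops):
        start = float(s)
        if s > 0:  # interpolate the upward crossing
            start = (s - 1) + (critical_t - a[s - 1]) / (a[s] - a[s - 1])
        end = float(e - 1)
        if e < len(a):
            end = (e - 1) + (a[e - 1] - critical_t) / (a[e - 1] - a[e])
        extent = end - start
        clusters.append({
            "start_pct": start, "end_pct": end,
            "p": _cluster_p(extent, critical_t, df, fwhm, alpha),
        })
    return clusters


def _cluster_p(extent_nodes: float, u: float, df: int, fwhm: float,
               alpha: float) -> float:
    if not np.isfinite(fwhm) or fwhm <= 0:
        return alpha
    resels = (N_NODES - 1) / fwhm
    e_clusters = 2 * resels * _ec_density_1d(u, df)     # two-tailed
    e_nodes = 2 * (N_NODES - 1) * stats.t.sf(u, df)
    if e_clusters <= 0 or e_nodes <= 0:
        return alpha
    mean_extent = e_nodes / e_clusters
    p = 1.0 - np.exp(-e_clusters * np.exp(-extent_nodes / mean_extent))
    return float(min(alpha, max(p, np.finfo(float).tiny)))


def paired_spm(A, B, alpha: float = 0.05, m_comparisons: int = 1) -> SPMResult:
    """Full paired SPM stage: t-field, smoothness, RFT threshold, clusters."""
    t, residuals, df = paired_t_field(A, B)
    fwhm = estimate_fwhm(residuals)
    tstar = rft_threshold(df, fwhm, alpha=alpha, m_comparisons=m_comparisons)
    clusters = suprathreshold_clusters(t, tstar, df=df, fwhm=fwhm, alpha=alpha)
    return SPMResult(t, df, fwhm, tstar, clusters, alpha, m_comparisons)


def permutation_spm(A, B, n_perm: int = 10000, seed: int = 0,
                    alpha: float = 0.05) -> float:
    """Sign-flip permutation threshold on the max-|t| statistic (oracle).

    Exhaustive over the 2^n sign flips when that is at most ``n_perm``
    (then deterministic and independent of the seed), otherwise a seeded
    random subset.  Returns the (1 - alpha) quantile of the max-|t|
    distribution; used to validate :func:`rft_threshold`.
    """
    d = _paired_differences(A, B)
    n = d.shape[0]
    if 2 ** n <= n_perm:
        signs = np.array(np.meshgrid(*[[1.0, -1.0]] * n)).reshape(n, -1).T
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    flipped_mean = signs @ d / n
    # sd of sign-flipped differences: E[x^2] is flip-invariant
    sq = (d ** 2).sum(axis=0)
    var = (sq - n * flipped_mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(var > 0, np.abs(flipped_mean) / np.sqrt(var / n), 0.0)
    tmax = tstat.max(axis=1)
    return float(np.quantile(tmax, 1 - alpha))
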