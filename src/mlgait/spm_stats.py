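"""Scalar and one-dimensional (SPM) paired t-tests.

Scalar paired t-tests compare per-subject spatio-temporal parameters between
two measurement systems.  The 1D test computes a pointwise paired t statistic
over the 101 nodes of a gait-cycle curve and controls the family-wise error
rate either by 1D random field theory (expected Euler characteristic of a t
field, with smoothness estimated from the standardized residual gradients) or
by a sign-flip permutation distribution of the maximum |t|.

Tests are two-sided throughout.  The RFT threshold is capped at the
Bonferroni bound over nodes, so for any finite smoothness it lies between the
scalar critical value and the Bonferroni-over-nodes critical value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from mlgait.errors import ConfigError, DataError

_4LOG2 = 4.0 * math.log(2.0)
EXHAUSTIVE_LIMIT = 10_000          # enumerate all sign flips when 2^n <= this
DEFAULT_N_PERMUTATIONS = 1_000


@dataclass(frozen=True)
class ScalarTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False       # zero variance of paired differences


def paired_ttest_scalar(a: np.ndarray, b: np.ndarray) -> ScalarTResult:
    """Two-sided paired t-test on per-subject values.

    Zero variance of the differences yields a degenerate-case flag with the
    convention t = 0, p = 1 for identical inputs and t = +/-inf, p = 0 for a
    constant nonzero difference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired samples must be equal-length 1D arrays")
    n = a.size
    if n < 3:
        raise DataError(f"need n >= 3 pairs, got {n}")
    d = a - b
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return ScalarTResult(0.0, df, 1.0, degenerate=True)
        return ScalarTResult(math.copysign(math.inf, md), df, 0.0, degenerate=True)
    t = md / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ScalarTResult(float(t), df, p, degenerate=False)


# ---------------------------------------------------------------------------
# 1D SPM paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    """Maximal suprathreshold run of the |t| curve."""

    start_pct: float
    end_pct: float
    extent_pct: float
    p: float

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.start_pct <= hi and self.end_pct >= lo


@dataclass(frozen=True)
class SPM1DResult:
    t_curve: np.ndarray
    critical_threshold: float
    alpha: float
    estimated_smoothness_fwhm: float     # in nodes (= % of cycle on a 101 grid)
    clusters: tuple[Cluster, ...]
    method: str                          # "rft" | "permutation"
    df: int
    degenerate: bool = False

    @property
    def reject_any(self) -> bool:
        return len(self.clusters) > 0


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Global smoothness (FWHM, in nodes) of residual fields (n x Q).

    Standard 1D RFT estimator: variance of the gradient of the
    sum-of-squares-normalized residual fields.
    """
    residuals = np.asarray(residuals, float)
    ssq = (residuals ** 2).sum(axis=0)
    grad = np.gradient(residuals, axis=1)
    v = (grad ** 2).sum(axis=0)
    good = ssq > 0
    if not good.any():
        return float("inf")
    v = v[good] / ssq[good]
    resels_per_node = np.sqrt(v / _4LOG2)
    mean_rpn = resels_per_node.mean()
    if mean_rpn <= 0:
        return float("inf")
    return float(1.0 / mean_rpn)


def _ec_density_t(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of a 1D t field thresholded at u."""
    rho0 = float(stats.t.sf(u, df))
    rho1 = (math.sqrt(_4LOG2) / (2.0 * math.pi)
            * (1.0 + u * u / df) ** (-(df - 1) / 2.0))
    return rho0 + resels * rho1


def rft_threshold(alpha: float, df: int, n_nodes: int, fwhm: float) -> float:
    """Two-sided RFT critical |t| threshold for a 1D field.

    Solves E[EC](u) = alpha/2 with resels = (n_nodes - 1)/FWHM, bounded
    below by the scalar two-sided critical value and above by the
    Bonferroni-over-nodes critical value.
    """
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    t_scalar = float(stats.t.isf(alpha / 2.0, df))
    t_bonf = float(stats.t.isf(alpha / (2.0 * n_nodes), df))
    if not np.isfinite(fwhm) or fwhm <= 0:
        return t_scalar if fwhm > 0 or not np.isfinite(fwhm) else t_bonf
    resels = (n_nodes - 1) / fwhm
    target = alpha / 2.0
    if _ec_density_t(t_scalar, df, resels) <= target:
        return t_scalar
    hi = t_bonf
    if _ec_density_t(hi, df, resels) > target:
        return t_bonf  # Bonferroni cap
    u = brentq(lambda x: _ec_density_t(x, df, resels) - target, t_scalar, hi)
    return float(u)


def _t_curve(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise paired t statistic of difference fields d (n x Q)."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / math.sqrt(n)), 0.0)
    return t, sd


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (start, end inclusive, node indices) where |t| > threshold."""
    above = np.abs(t) > threshold
    runs = []
    i = 0
    q = above.size
    while i < q:
        if above[i]:
            j = i
            while j + 1 < q and above[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _rft_cluster_p(extent_nodes: float, u: float, df: int, n_nodes: int,
                   fwhm: float, alpha_sides: int = 2) -> float:
    """Cluster-extent p-value via the Poisson-clumping approximation."""
    resels = (n_nodes - 1) / fwhm
    em = alpha_sides * _ec_density_t(u, df, resels)          # expected clusters
    en = alpha_sides * n_nodes * float(stats.t.sf(u, df)) / fwhm  # resels above u
    if em <= 0 or en <= 0:
        return 1.0
    k_resels = extent_nodes / fwhm
    beta = (math.gamma(1.5) * em / en) ** 2
    p_ext = math.exp(-beta * k_resels ** 2)
    return float(min(1.0, max(np.finfo(float).tiny, 1.0 - math.exp(-em * p_ext))))


def _sign_matrix(n: int, rng: np.random.Generator | None,
                 n_permutations: int) -> np.ndarray:
    if 2 ** n <= EXHAUSTIVE_LIMIT:
        return np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    if rng is None:
        raise ConfigError(
            f"2^{n} sign flips exceed the exhaustive limit; a seed is required "
            "for Monte-Carlo permutation")
    return rng.choice((1.0, -1.0), size=(n_permutations, n))


def paired_ttest_1d(curves_a: np.ndarray, curves_b: np.ndarray,
                    alpha: float = 0.05, method: str = "rft",
                    seed: int | None = None,
                    n_permutations: int = DEFAULT_N_PERMUTATIONS) -> SPM1DResult:
    """1D paired t-test over gait-cycle curves (subjects x nodes).

    ``method`` "rft" uses the random-field-theory threshold; "permutation"
    uses the (1 - alpha) quantile of the max-|t| sign-flip distribution
    (exhaustive when feasible, otherwise Monte-Carlo using ``seed``).
    """
    a = np.asarray(curves_a, float)
    b = np.asarray(curves_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise DataError("curve arrays must share shape (subjects, nodes)")
    n, q = a.shape
    if n < 3:
        raise DataError(f"need n >= 3 subjects, got {n}")
    d = a - b
    t, sd = _t_curve(d)
    df = n - 1
    residuals = d - d.mean(axis=0)
    fwhm = estimate_fwhm(residuals)
    degenerate = bool(np.all(sd == 0))

    if method == "rft":
        tstar = rft_threshold(alpha, df, q, fwhm)
        runs = _find_clusters(t, tstar)
        clusters = tuple(
            Cluster(float(i), float(j), float(j - i + 1),
                    _rft_cluster_p(j - i + 1, tstar, df, q,
                                   fwhm if np.isfinite(fwhm) and fwhm > 0 else 1.0))
            for i, j in runs)
    elif method == "permutation":
        rng = None if seed is None else np.random.default_rng(seed)
        signs = _sign_matrix(n, rng, n_permutations)
        m = signs @ d / n
        e2 = (d ** 2).sum(axis=0) / n
        var = np.maximum(e2 - m ** 2, 0.0) * (n / (n - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(var > 0, m / np.sqrt(var / n), 0.0)
        max_t = np.abs(t_perm).max(axis=1)
        tstar = float(np.quantile(max_t, 1.0 - alpha))
        runs = _find_clusters(t, tstar)
        clusters = tuple(
            Cluster(float(i), float(j), float(j - i + 1),
                    float(np.mean(max_t >= np.abs(t[i:j + 1]).max())))
            for i, j in runs)
    else:
        raise ConfigError(f"unknown method {method!r}")

    return SPM1DResult(t, float(tstar), alpha, fwhm, clusters, method, df,
                       degenerate=degenerate)


def smooth_gaussian_fields(n: int, n_nodes: int, fwhm: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smooth Gaussian random fields (n x n_nodes).

    White noise convolved with a Gaussian kernel whose FWHM (in nodes)
    matches the requested smoothness; used for null calibration.
    """
    sigma = fwhm / math.sqrt(8.0 * math.log(2.0))
    pad = int(math.ceil(4 * sigma))
    noise = rng.standard_normal((n, n_nodes + 2 * pad))
    smooth = gaussian_filter1d(noise, sigma, axis=1)
    smooth = smooth[:, pad:pad + n_nodes]
    # analytic variance of Gaussian-smoothed unit white noise
    scale = math.sqrt(1.0 / (2.0 * sigma * math.sqrt(math.pi)))
    return smooth / scale


# ---------------------------------------------------------------------------
# System comparison report
# ---------------------------------------------------------------------------

@dataclass
class SystemComparison:
    """Scalar tests on the six parameters + 1D tests on the five angles."""

    param_tests: dict[str, ScalarTResult]
    angle_tests: dict[str, SPM1DResult]
    alpha: float
    bonferroni_note: dict[str, bool] = field(default_factory=dict)

    def report_table(self):
        import pandas as pd

        rows = []
        for name, r in self.param_tests.items():
            rows.append({"variable": name, "kind": "parameter", "t": r.t,
                         "df": r.df, "p": r.p, "degenerate": r.degenerate,
                         "n_clusters": None})
        for name, r in self.angle_tests.items():
            rows.append({"variable": name, "kind": "angle_curve",
                         "t": float(np.max(np.abs(r.t_curve))), "df": r.df,
                         "p": min((c.p for c in r.clusters), default=1.0),
                         "degenerate": r.degenerate,
                         "n_clusters": len(r.clusters)})
        return pd.DataFrame(rows)


def compare_systems(params_a, params_b, angles_a, angles_b,
                    alpha: float = 0.05, method: str = "rft",
                    seed: int | None = None) -> SystemComparison:
    """Full two-system comparison.

    ``params_a/b``: mapping parameter name -> per-subject values (paired).
    ``angles_a/b``: mapping angle name -> (subjects x 101) curve arrays.
    No multiplicity correction is applied across the tests (conservative
    toward finding differences); a Bonferroni-adjusted conclusion per angle
    cluster is reported alongside.
    """
    if set(params_a) != set(params_b) or set(angles_a) != set(angles_b):
        raise DataError("the two systems must provide the same variables")
    param_tests = {name: paired_ttest_scalar(np.asarray(params_a[name], float),
                                             np.asarray(params_b[name], float))
                   for name in params_a}
    angle_tests = {}
    bonf = {}
    n_angles = max(len(angles_a), 1)
    for name in angles_a:
        res = paired_ttest_1d(np.asarray(angles_a[name], float),
                              np.asarray(angles_b[name], float),
                              alpha=alpha, method=method, seed=seed)
        angle_tests[name] = res
        bonf[name] = any(c.p < alpha / n_angles for c in res.clusters)
    return SystemComparison(param_tests, angle_tests, alpha, bonf)
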