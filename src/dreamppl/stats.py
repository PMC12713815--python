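"""Two-sample statistics: 1D permutation test, two-dimensional
Kolmogorov–Smirnov (Fasano–Franceschini) test, Spearman correlation, and
Holm step-down multiple-comparison correction.

The 1D permutation test uses the absolute difference of group means as its
statistic and the add-one Monte-Carlo p-value
``p = (1 + #{null >= observed}) / (1 + B)``, which is valid at any number of
permutations; an exact mode enumerates all label assignments instead.

The 2D test follows the Fasano–Franceschini construction: quadrants are
centred at every data point of each sample in turn, ``D_k`` is the largest
absolute difference of the two empirical quadrant fractions over the points
of sample ``k``, and ``D = (D_1 + D_2) / 2``.  Points landing exactly on a
quadrant boundary are counted in the lower/left-closed quadrant.  P-values
come either from pooled-permutation resampling or from the large-sample
analytic approximation with the sample-correlation correction
(Numerical-Recipes form), flagged as unreliable below effective n of 20.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

from .errors import InvalidArgumentError


@dataclass
class TwoSampleTestResult:
    """Outcome of a two-sample test, with enough metadata to reproduce it."""

    statistic_name: str  # "mean_diff" | "D2"
    statistic: float
    p_raw: float
    n1: int
    n2: int
    n_permutations: int
    seed: int | None = None
    p_adjusted: float | None = None
    method: str = "monte_carlo"

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "n1": self.n1,
            "n2": self.n2,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# 1D permutation test
# ---------------------------------------------------------------------------

def permutation_test_1d(
    a: Sequence[float],
    b: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "monte_carlo",
) -> TwoSampleTestResult:
    """Two-sided random permutation test on the absolute mean difference.

    ``method="monte_carlo"`` (default) draws ``n_permutations`` random
    re-assignments of the pooled values to groups of the original sizes and
    applies the add-one rule.  ``method="exact"`` enumerates all
    ``C(n1+n2, n1)`` assignments and returns the exact proportion with a
    null statistic at least as large as the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both samples must be nonempty")
    if method not in ("monte_carlo", "exact"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())

    if method == "exact":
        total = math.comb(n1 + n2, n1)
        count = 0
        psum = pooled.sum()
        for combo in combinations(range(n1 + n2), n1):
            s1 = pooled[list(combo)].sum()
            stat = abs(s1 / n1 - (psum - s1) / n2)
            if stat >= observed - 1e-12:
                count += 1
        p = count / total
        return TwoSampleTestResult(
            "mean_diff", float(observed), float(p), n1, n2, total, seed, method="exact"
        )

    if n_permutations < 1:
        raise InvalidArgumentError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    mat = np.tile(pooled, (n_permutations, 1))
    rng.permuted(mat, axis=1, out=mat)
    null = np.abs(mat[:, :n1].mean(axis=1) - mat[:, n1:].mean(axis=1))
    p = (1 + int(np.sum(null >= observed - 1e-12))) / (1 + n_permutations)
    return TwoSampleTestResult(
        "mean_diff", float(observed), float(p), n1, n2, n_permutations, seed
    )


# ---------------------------------------------------------------------------
# 2D Kolmogorov–Smirnov (Fasano–Franceschini)
# ---------------------------------------------------------------------------

def _as_points(sample) -> np.ndarray:
    pts = np.asarray(sample, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("a 2D sample must have shape (n, 2)")
    if pts.shape[0] == 0:
        raise InvalidArgumentError("2D samples must be nonempty")
    if not np.all(np.isfinite(pts)):
        raise InvalidArgumentError("2D sample coordinates must be finite")
    return pts


def _max_quadrant_diff(
    centers: np.ndarray, s1: np.ndarray, s2: np.ndarray, chunk: int = 512
) -> float:
    """Max over centers and the four closed-left/low quadrants of the
    absolute difference in empirical fractions of s1 vs s2."""
    best = 0.0
    for start in range(0, centers.shape[0], chunk):
        c = centers[start : start + chunk]
        left1 = s1[None, :, 0] <= c[:, None, 0]
        low1 = s1[None, :, 1] <= c[:, None, 1]
        left2 = s2[None, :, 0] <= c[:, None, 0]
        low2 = s2[None, :, 1] <= c[:, None, 1]
        for lx, ly in ((1, 1), (1, 0), (0, 1), (0, 0)):
            f1 = ((left1 == bool(lx)) & (low1 == bool(ly))).mean(axis=1)
            f2 = ((left2 == bool(lx)) & (low2 == bool(ly))).mean(axis=1)
            best = max(best, float(np.max(np.abs(f1 - f2))))
    return best


def ks2d_statistic(sample1, sample2) -> float:
    """Fasano–Franceschini two-sample 2D KS statistic ``D in [0, 1]``."""
    s1 = _as_points(sample1)
    s2 = _as_points(sample2)
    d1 = _max_quadrant_diff(s1, s1, s2)
    d2 = _max_quadrant_diff(s2, s1, s2)
    return 0.5 * (d1 + d2)


def _safe_pearson(pts: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.ptp(pts[:, 0]) == 0 or np.ptp(pts[:, 1]) == 0 or pts.shape[0] < 2:
            return 0.0
        r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
    return 0.0 if not np.isfinite(r) else float(r)


def ks2d_pvalue(
    D: float,
    n1: int,
    n2: int,
    mode: str = "analytic",
    n_permutations: int = 1000,
    seed: int | None = None,
    sample1=None,
    sample2=None,
) -> float:
    """P-value for an observed 2D KS statistic.

    ``mode="analytic"`` uses the large-sample approximation
    ``p = Q_KS( D*sqrt(n) / (1 + sqrt(1 - r^2) (0.25 - 0.75/sqrt(n))) )``
    with ``n = n1*n2/(n1+n2)`` and ``r^2 = (r1^2 + r2^2)/2`` the mean squared
    per-sample Pearson correlation (requires ``sample1``/``sample2`` for the
    correlation correction; without them ``r = 0`` is assumed).  A warning is
    emitted when effective n < 20, where the approximation is unreliable.

    ``mode="permutation"`` pools the points, re-splits them
    ``n_permutations`` times and applies the add-one rule (requires both
    samples).
    """
    if not 0.0 <= D <= 1.0 + 1e-12:
        raise InvalidArgumentError(f"D must be in [0, 1], got {D}")
    if mode == "analytic":
        n_eff = n1 * n2 / (n1 + n2)
        if n_eff < 20:
            warnings.warn(
                "2D KS analytic p-value is unreliable for effective n < 20",
                stacklevel=2,
            )
        rr = 0.0
        if sample1 is not None and sample2 is not None:
            r1 = _safe_pearson(_as_points(sample1))
            r2 = _safe_pearson(_as_points(sample2))
            rr = 0.5 * (r1 * r1 + r2 * r2)
        sqen = math.sqrt(n_eff)
        z = D * sqen / (1.0 + math.sqrt(1.0 - rr) * (0.25 - 0.75 / sqen))
        return float(min(1.0, max(0.0, special.kolmogorov(z))))
    if mode == "permutation":
        if sample1 is None or sample2 is None:
            raise InvalidArgumentError("permutation mode requires both samples")
        s1 = _as_points(sample1)
        s2 = _as_points(sample2)
        pooled = np.vstack([s1, s2])
        rng = np.random.default_rng(seed)
        count = 0
        n = pooled.shape[0]
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            d_null = ks2d_statistic(pooled[perm[: s1.shape[0]]], pooled[perm[s1.shape[0] :]])
            if d_null >= D - 1e-12:
                count += 1
        return (1 + count) / (1 + n_permutations)
    raise InvalidArgumentError(f"unknown mode {mode!r}")


def ks2d_test(
    sample1,
    sample2,
    mode: str = "analytic",
    n_permutations: int = 1000,
    seed: int | None = None,
) -> TwoSampleTestResult:
    """Convenience wrapper: statistic plus p-value as one result record."""
    s1 = _as_points(sample1)
    s2 = _as_points(sample2)
    D = ks2d_statistic(s1, s2)
    p = ks2d_pvalue(
        D, s1.shape[0], s2.shape[0], mode=mode,
        n_permutations=n_permutations, seed=seed, sample1=s1, sample2=s2,
    )
    return TwoSampleTestResult(
        "D2", float(D), float(p), s1.shape[0], s2.shape[0],
        n_permutations if mode == "permutation" else 0, seed, method=mode,
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    constant_input: bool = False


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (ties get average ranks; p from the
    large-sample t approximation).  Constant input yields a flagged
    missing result instead of an exception."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(math.nan, math.nan, int(x.size), constant_input=True)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), int(x.size))


# ---------------------------------------------------------------------------
# Holm step-down correction
# ---------------------------------------------------------------------------

def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order.

    With ascending raw p-values ``p_(1) <= ... <= p_(m)``,
    ``adj_(i) = max_{j<=i} min(1, (m - j + 1) * p_(j))``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()
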