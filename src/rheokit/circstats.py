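"""Circular descriptive and inferential statistics on heading angles.

All public functions take angles in degrees.  The mean resultant length
rho is the length of the average unit vector (1 = perfect alignment,
0 = uniform); angular variance is 1 - rho.  Group comparisons are made on
one mean angle per fish, never on pooled frames, to avoid
pseudoreplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import InsufficientDataError, ParameterError, wrap_degrees


@dataclass
class CircularSummary:
    n: int
    theta: float            # deg, grand mean direction (NaN when rho == 0)
    rho: float              # mean resultant length in [0, 1]
    angular_variance: float  # 1 - rho


@dataclass
class CircularTestResult:
    test: str               # "v_test" | "watson_wheeler"
    statistic: float
    p: float
    df: int | None = None   # Watson-Wheeler only: 2 (k - 1)
    mu: float | None = None  # V-test only: hypothesized direction, deg
    method: str = ""


def _to_rad(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float).ravel()
    a = a[np.isfinite(a)]
    return np.radians(a)


def circular_mean(angles) -> float:
    """Circular mean direction in degrees; NaN for an empty/uniform sample."""
    a = _to_rad(angles)
    if a.size == 0:
        return float("nan")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        return float("nan")
    return wrap_degrees(np.degrees(np.arctan2(s, c)))


def mean_resultant(angles) -> CircularSummary:
    """Mean direction theta and resultant length rho of a circular sample."""
    a = _to_rad(angles)
    if a.size == 0:
        raise InsufficientDataError("mean_resultant needs at least one angle")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    rho = float(np.hypot(s, c))
    theta = wrap_degrees(np.degrees(np.arctan2(s, c))) if rho > 1e-12 else float("nan")
    return CircularSummary(n=int(a.size), theta=theta, rho=min(rho, 1.0),
                           angular_variance=1.0 - min(rho, 1.0))


def v_test(angles, mu: float = 0.0, method: str = "auto",
           n_mc: int = 10_000, rng=None) -> CircularTestResult:
    """Rayleigh V-test of uniformity against concentration toward ``mu``.

    V = n * rho * cos(theta - mu); the standardized statistic
    u = V * sqrt(2 / n) is referred to the standard normal upper tail.
    For n < 5 (or ``method='mc'``) the p-value is instead calibrated by
    Monte-Carlo sampling of the uniform null.
    """
    a = _to_rad(angles)
    n = a.size
    if n == 0:
        raise InsufficientDataError("v_test needs at least one angle")
    summ = mean_resultant(angles)
    theta = summ.theta if np.isfinite(summ.theta) else mu
    V = n * summ.rho * np.cos(np.radians(theta - mu))
    u = V * np.sqrt(2.0 / n)
    if method == "auto":
        method = "normal" if n >= 5 else "mc"
    if method == "normal":
        p = float(stats.norm.sf(u))
    elif method == "mc":
        rng = np.random.default_rng(rng)
        null = rng.uniform(0, 2 * np.pi, size=(n_mc, n))
        s = np.sin(null).mean(axis=1)
        c = np.cos(null).mean(axis=1)
        mu_r = np.radians(mu)
        V0 = n * (c * np.cos(mu_r) + s * np.sin(mu_r))  # n*rho*cos(theta-mu)
        p = float((1 + np.sum(V0 >= V)) / (1 + n_mc))
    else:
        raise ParameterError("method must be 'auto', 'normal' or 'mc'")
    return CircularTestResult(test="v_test", statistic=float(V), p=p,
                              mu=mu, method=method)


def _ww_statistic(gamma: np.ndarray, sizes: np.ndarray) -> float:
    """Watson-Wheeler W from pooled uniform scores split into groups."""
    W = 0.0
    offset = 0
    for n_g in sizes:
        g = gamma[offset : offset + n_g]
        W += (np.cos(g).sum() ** 2 + np.sin(g).sum() ** 2) / n_g
        offset += n_g
    return 2.0 * W


def watson_wheeler(*groups, method: str = "auto", n_perm: int = 9_999,
                   rng=None) -> CircularTestResult:
    """Watson-Wheeler k-sample test for a difference in mean direction or
    angular variance (the test does not say which differs).

    Pooled circular ranks (mid-ranks for ties) are mapped to uniform scores
    gamma_i = 2*pi*rank_i / N; W = 2 * sum_g (C_g^2 + S_g^2) / n_g is
    referred to chi-square with 2(k-1) df after a finite-sample moment
    correction, or to a permutation null when any group has n < 10
    (or ``method='permutation'``).
    """
    if len(groups) < 2:
        raise ParameterError("watson_wheeler needs at least 2 groups")
    arrs = [_to_rad(g) for g in groups]
    sizes = np.array([a.size for a in arrs])
    if np.any(sizes == 0):
        raise InsufficientDataError("every group needs at least one angle")
    k = len(arrs)
    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = stats.rankdata(np.mod(pooled, 2 * np.pi), method="average")
    gamma = 2 * np.pi * ranks / N
    W = _ww_statistic(gamma, sizes)
    df = 2 * (k - 1)
    if method == "auto":
        method = "chi2" if np.all(sizes >= 10) else "permutation"
    if method == "chi2":
        # finite-sample moment correction: under label permutation the exact
        # mean of W is df * N / (N - 1); rescaling matches the chi2 mean
        p = float(stats.chi2.sf(W * (N - 1) / N, df))
    elif method == "permutation":
        rng = np.random.default_rng(rng)
        # vectorized label shuffles: permute score order, reuse group blocks
        perm = np.argsort(rng.random((n_perm, N)), axis=1)
        G = gamma[perm]
        W0 = np.zeros(n_perm)
        offset = 0
        for n_g in sizes:
            block = G[:, offset : offset + n_g]
            W0 += (
                np.cos(block).sum(axis=1) ** 2 + np.sin(block).sum(axis=1) ** 2
            ) / n_g
            offset += n_g
        W0 *= 2.0
        count = int(np.sum(W0 >= W - 1e-12))
        p = float((1 + count) / (1 + n_perm))
    else:
        raise ParameterError("method must be 'auto', 'chi2' or 'permutation'")
    return CircularTestResult(test="watson_wheeler", statistic=float(W), p=p,
                              df=df, method=method)


def per_fish_means(series_list, epoch: str | None = None) -> np.ndarray:
    """One circular mean heading per fish (the unit of group analysis).

    ``epoch`` restricts bins to one stimulus window; valid bins weight
    equally.  Fish with no valid bin in the window yield NaN and are
    dropped by the circular statistics downstream.
    """
    out = []
    for s in series_list:
        df = s.df
        # copy: to_numpy on a bool column may be a zero-copy view
        sel = df["valid"].to_numpy(dtype=bool).copy()
        if epoch is not None:
            sel &= (df["epoch"] == epoch).to_numpy()
        out.append(circular_mean(df["heading"].to_numpy(dtype=float)[sel]))
    return np.asarray(out)
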