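"""Degree distributions, discrete power-law fitting and KS goodness of fit.

The model is the discrete power law ``P(k) = k^(-gamma) / zeta(gamma, x_min)``
for integer ``k >= x_min``, with the Hurwitz zeta as normalizer. The exponent
is fitted by numerical maximum likelihood on the tail; when no lower cut-off
is supplied, ``x_min`` is chosen as the candidate minimizing the
Kolmogorov–Smirnov distance between the empirical tail and the fitted model.
Goodness of fit uses the semiparametric bootstrap: synthetic datasets are
drawn from the fitted model (tail) and resampled from the data (body),
refitted from scratch, and the p-value is the fraction whose KS distance
exceeds the observed one. A scale-free network is one whose degree
distribution survives this test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "PowerLawFit",
    "degree_histogram",
    "fit_power_law",
    "ks_gof",
    "sample_power_law",
]

MIN_TAIL = 50  # fewer tail observations cannot pin an exponent

_GAMMA_LO, _GAMMA_HI = 1.01, 8.0


@dataclass
class PowerLawFit:
    """Fitted discrete power law on the degree tail ``k >= x_min``."""

    gamma: float
    x_min: int
    ks_stat: float
    n_tail: int
    p_value: float | None = None


def degree_histogram(net: nx.Graph, normalized: bool = False) -> pd.DataFrame:
    """Rows ``(k, count)`` for every observed degree; frequencies sum to 1
    when ``normalized``."""
    degs = np.array([d for _, d in net.degree()], dtype=int)
    ks, counts = np.unique(degs, return_counts=True)
    col = "frequency" if normalized else "count"
    vals = counts / counts.sum() if normalized else counts
    return pd.DataFrame({"k": ks, col: vals})


def _neg_loglike(gamma: float, x_min: int, n: int, sum_log: float) -> float:
    return n * np.log(zeta(gamma, x_min)) + gamma * sum_log


def _mle_gamma(tail: np.ndarray, x_min: int) -> float:
    res = minimize_scalar(
        _neg_loglike,
        bounds=(_GAMMA_LO, _GAMMA_HI),
        args=(x_min, tail.size, float(np.log(tail).sum())),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, gamma: float, x_min: int) -> float:
    """Sup distance between empirical tail CDF and the fitted discrete CDF."""
    values, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / tail.size
    z0 = zeta(gamma, x_min)
    model_cdf = 1.0 - zeta(gamma, values + 1) / z0
    return float(np.max(np.abs(ecdf - model_cdf)))


def fit_power_law(degrees, x_min: int | None = None) -> PowerLawFit:
    """Fit the discrete power law to a list of positive integer degrees.

    With ``x_min`` given, only the exponent is estimated on the tail
    ``k >= x_min``. Otherwise every observed degree value leaving at least
    ``MIN_TAIL`` tail observations is tried as cut-off and the one minimizing
    the KS distance wins.
    """
    degs = np.asarray(degrees, dtype=int)
    degs = degs[degs > 0]
    if degs.size == 0:
        raise ValueError("no positive degrees to fit")
    if np.unique(degs).size == 1:
        raise ValueError("all degrees equal; there is no scale to fit")

    if x_min is not None:
        if x_min < 1:
            raise ValueError("x_min must be >= 1")
        tail = degs[degs >= x_min]
        if tail.size < MIN_TAIL:
            raise ValueError(
                f"only {tail.size} tail observations >= x_min={x_min}; "
                f"need at least {MIN_TAIL}"
            )
        gamma = _mle_gamma(tail, x_min)
        return PowerLawFit(gamma, int(x_min), _ks_distance(tail, gamma, x_min),
                           int(tail.size))

    candidates = [int(v) for v in np.unique(degs)
                  if (degs >= v).sum() >= MIN_TAIL]
    if not candidates:
        raise ValueError(
            f"no cut-off leaves {MIN_TAIL} tail observations; dataset too small"
        )
    best: PowerLawFit | None = None
    for xm in candidates:
        tail = degs[degs >= xm]
        if np.unique(tail).size == 1:
            continue
        gamma = _mle_gamma(tail, xm)
        ks = _ks_distance(tail, gamma, xm)
        if best is None or ks < best.ks_stat:
            best = PowerLawFit(gamma, xm, ks, int(tail.size))
    if best is None:
        raise ValueError("degenerate tail at every candidate cut-off")
    return best


def sample_power_law(
    n: int,
    gamma: float,
    x_min: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Exact inverse-CDF draws from the discrete power law.

    The CDF is tabulated over ``[x_min, x_min + 2^16)``; the negligible
    probability mass beyond the table (< 1e-7 for gamma >= 2) is inverted by
    bisection on the Hurwitz-zeta survival function, so draws are exact.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    rng = np.random.default_rng(rng)
    table_n = 1 << 16
    ks = np.arange(x_min, x_min + table_n, dtype=float)
    z0 = zeta(gamma, x_min)
    pmf = ks ** (-gamma) / z0
    cdf = np.cumsum(pmf)
    u = rng.random(n)
    out = x_min + np.searchsorted(cdf, u, side="left")
    over = np.flatnonzero(u >= cdf[-1])
    for i in over:
        lo, hi = x_min + table_n - 1, x_min + table_n
        # survival S(k) = zeta(gamma, k+1)/z0; find smallest k with CDF >= u
        while 1.0 - zeta(gamma, hi + 1) / z0 < u[i]:
            lo, hi = hi, hi * 2
        while lo + 1 < hi:
            mid = (lo + hi) // 2
            if 1.0 - zeta(gamma, mid + 1) / z0 >= u[i]:
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return out.astype(int)


def ks_gof(
    fit: PowerLawFit,
    degrees,
    n_boot: int = 100,
    seed: int | None = None,
) -> float:
    """Semiparametric bootstrap p-value for the power-law hypothesis.

    Each synthetic dataset draws, per observation, from the fitted tail model
    with probability ``n_tail / n`` and otherwise resamples the observed body
    below ``x_min``; the dataset is refitted from scratch (including cut-off
    selection) and its KS distance compared with the observed one. Large p
    means the power law is a plausible generator of the data.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be >= 20 for a usable p-value")
    degs = np.asarray(degrees, dtype=int)
    degs = degs[degs > 0]
    rng = np.random.default_rng(seed)
    body = degs[degs < fit.x_min]
    p_tail = fit.n_tail / degs.size
    exceed = 0
    for _ in range(n_boot):
        take_tail = rng.random(degs.size) < p_tail
        n_t = int(take_tail.sum())
        synth = np.empty(degs.size, dtype=int)
        synth[take_tail] = sample_power_law(n_t, fit.gamma, fit.x_min, rng)
        n_b = degs.size - n_t
        synth[~take_tail] = rng.choice(body, size=n_b) if body.size else \
            sample_power_law(n_b, fit.gamma, fit.x_min, rng)
        try:
            refit = fit_power_law(synth)
        except ValueError:
            continue
        if refit.ks_stat > fit.ks_stat:
            exceed += 1
    return exceed / n_boot
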