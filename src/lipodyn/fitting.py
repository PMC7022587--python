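"""Stretched-exponential fitting primitives shared by the HDX modules.

A deuterium-uptake curve of a set of amides with heterogeneous rates is
compactly described by one or two stretched-exponential phases,

    DI(t) = sum_p N_p * (1 - exp(-(k_p t)^beta_p)),   0 < beta_p <= 1,

where N_p is the (continuous) number of sites in phase p, k_p the average
rate and beta_p the heterogeneity exponent (beta = 1: a single shared rate).

All fits are performed in dimensionless time tau = t / t[0], which makes the
recovered rates exactly equivariant under a uniform rescaling of time (the
property the protection-factor pipeline relies on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["stretched_exp", "fit_single_stretched", "fit_two_phase", "aic"]


def stretched_exp(t: np.ndarray, n: float, k: float, beta: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return n * (1.0 - np.exp(-np.power(np.maximum(k * t, 0.0), beta)))


def aic(rss: float, n_obs: int, n_par: int, floor: float) -> float:
    """Akaike criterion on Gaussian residuals; corrected form when it exists."""
    rss = max(rss, floor)
    val = n_obs * np.log(rss / n_obs) + 2 * n_par
    if n_obs - n_par - 1 > 0:
        val += 2.0 * n_par * (n_par + 1) / (n_obs - n_par - 1)
    return float(val)


def _guess_log_kappa(tau: np.ndarray, frac: np.ndarray) -> float:
    """Initial log(k*t0) from the time of half completion."""
    idx = np.searchsorted(frac, 0.5)
    idx = min(max(idx, 1), tau.size - 1)
    return float(-np.log(tau[idx]))


def fit_single_stretched(
    t: np.ndarray,
    di: np.ndarray,
    n_sites: float,
    beta_bounds: tuple[float, float] = (1e-3, 1.0),
) -> tuple[float, float, float]:
    """Fit DI(t) = n_sites*(1 - exp(-(k t)^beta)).  Returns (k 1/s, beta, rss)."""
    t = np.asarray(t, dtype=float)
    di = np.asarray(di, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 time points required")
    if np.any(t <= 0):
        raise ValueError("times must be positive for the stretched-exponential fit")
    t0 = t[0]
    tau = t / t0
    frac = np.clip(di / n_sites, 0.0, 1.0)

    def resid(p):
        log_kappa, beta = p
        return stretched_exp(tau, n_sites, np.exp(log_kappa), beta) - di

    best = None
    base_lk = _guess_log_kappa(tau, frac)
    for beta0 in (1.0, 0.7, 0.4):
        beta0 = float(np.clip(beta0, *beta_bounds))
        sol = least_squares(
            resid,
            x0=[base_lk, beta0],
            bounds=([-40.0, beta_bounds[0]], [40.0, beta_bounds[1]]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[2]:
            best = (float(np.exp(sol.x[0]) / t0), float(sol.x[1]), rss)
    return best


@dataclass(frozen=True)
class TwoPhaseResult:
    n_fast: float
    k_fast: float
    beta_fast: float
    n_slow: float
    k_slow: float
    beta_slow: float
    rss: float
    converged: bool = True


def fit_two_phase(
    t: np.ndarray,
    di: np.ndarray,
    n_exch: float,
    seed: int | None = 0,
    n_starts: int = 8,
    fix_total: bool = True,
    beta_bounds: tuple[float, float] = (0.3, 1.0),
) -> TwoPhaseResult:
    """Two-phase stretched-exponential fit with k_fast >= k_slow.

    Parameterized as (N_fast, log k_fast, beta_fast, log-rate gap >= 0,
    beta_slow); with ``fix_total`` the slow-site count is n_exch - N_fast,
    otherwise it is a free parameter.  Seeded multistart initialization.
    """
    t = np.asarray(t, dtype=float)
    di = np.asarray(di, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    t0 = t[0]
    tau = t / t0
    rng = np.random.default_rng(seed)

    def unpack(p):
        if fix_total:
            nf, lkf, bf, gap, bs = p
            ns = n_exch - nf
        else:
            nf, lkf, bf, gap, bs, ns = p
        return nf, np.exp(lkf), bf, ns, np.exp(lkf - gap), bs

    def resid(p):
        nf, kf, bf, ns, ks, bs = unpack(p)
        return stretched_exp(tau, nf, kf, bf) + stretched_exp(tau, ns, ks, bs) - di

    lo = [0.0, -40.0, beta_bounds[0], 0.0, beta_bounds[0]]
    hi = [n_exch, 40.0, beta_bounds[1], 60.0, beta_bounds[1]]
    if not fix_total:
        lo.append(0.0)
        hi.append(n_exch)

    span = max(np.log(tau[-1]), 1.0)
    best = None
    for s in range(n_starts):
        nf0 = n_exch * (0.25 + 0.5 * rng.random()) if s else n_exch / 2
        lkf0 = rng.uniform(-1.0, span) if s else 0.0
        gap0 = rng.uniform(1.0, span + 4.0) if s else span / 2 + 1.0
        x0 = [nf0, lkf0, 0.9, gap0, 0.9]
        if not fix_total:
            x0.append(n_exch - nf0)
        try:
            sol = least_squares(resid, x0=x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("two-phase fit failed to converge from any start")
    nf, kf, bf, ns, ks, bs = unpack(best[1])
    return TwoPhaseResult(
        float(nf), float(kf / t0), float(bf), float(ns), float(ks / t0), float(bs), best[0]
    )
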