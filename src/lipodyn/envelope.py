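"""From isotopic envelopes to deuterium incorporation.

Implements centroiding, back-exchange-corrected deuterium incorporation (DI)
from 0% / 80% deuterated controls, and deconvolution of bimodal envelopes —
two co-existing populations of the same peptide exchanging at different rates,
the signature of conformational heterogeneity — into (weight, mean-uptake)
pairs.

The mixture model ties each component to the peptide's measured 0% reference
envelope convolved with a binomial deuteration distribution, so the fitted
component keeps the peptide's real isotopic fine structure.  One- versus
two-component model choice uses a BIC-style penalty (two components must win
by more than ``BIMODAL_DELTA_BIC``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .isotopes import D_MASS_SHIFT, binomial_weights, convolve_peak_lists, merge_peaks

__all__ = [
    "Envelope",
    "DeconvolvedPair",
    "Component",
    "AbundanceResult",
    "TimeCourse",
    "DiResult",
    "BIMODAL_DELTA_BIC",
    "centroid",
    "compute_di",
    "deconvolve_bimodal",
    "relative_abundance",
]

TIME_CONTROL_0 = -1.0  # encodes the 0% deuterated control
TIME_CONTROL_80 = -2.0  # encodes the 80% deuterated control

#: two-component model must beat one component by this much BIC to call bimodal
BIMODAL_DELTA_BIC = 10.0


@dataclass(frozen=True)
class Envelope:
    """Isotopic peak list of one peptide at one charge state and time point."""

    peptide_id: str
    charge: int
    time: float  # s; -1 = 0% control, -2 = 80% control
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if np.any(inten < 0) or not np.any(inten > 0):
            raise ValueError("intensities must be >= 0 with at least one > 0")
        order = np.argsort(mz)
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


def centroid(env: Envelope) -> float:
    """Intensity-weighted mean m/z of the envelope."""
    tot = env.intensity.sum()
    if tot <= 0:
        raise ValueError("cannot centroid an all-zero envelope")
    return float((env.mz * env.intensity).sum() / tot)


@dataclass(frozen=True)
class DiResult:
    di: float  # back-exchange-corrected deuterons, D units
    di_raw: float  # uncorrected mass-domain shift, Da
    back_exchange_percent: float


def compute_di(
    cent_t: float,
    cent_0: float,
    cent_80: float,
    charge: int,
    n_exch: int,
    control_fraction: float = 0.8,
    clamp_tolerance: float = 0.1,
) -> DiResult:
    """Deuterium incorporation from centroids, corrected with the 80% control.

    DI = (cent_t - cent_0) / (cent_80 - cent_0) * control_fraction * n_exch;
    the charge cancels in the centroid ratio.  Also reports the raw
    mass-domain shift and the apparent back-exchange percentage of the run.
    Slightly negative DI (early-time noise) is clamped to 0; beyond
    ``clamp_tolerance`` D a warning is raised.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if cent_80 <= cent_0:
        raise ValueError("80% control centroid must exceed the 0% control centroid")
    di = (cent_t - cent_0) / (cent_80 - cent_0) * control_fraction * n_exch
    di_raw = (cent_t - cent_0) * charge
    back_ex = (1.0 - (cent_80 - cent_0) * charge / (control_fraction * n_exch * D_MASS_SHIFT)) * 100.0
    if di < 0:
        if di < -clamp_tolerance:
            warnings.warn(
                f"centroid below the 0% control by {-di:.2f} D; clamping DI to 0",
                stacklevel=2,
            )
        di = 0.0
    return DiResult(float(di), float(di_raw), float(back_ex))


@dataclass(frozen=True)
class Component:
    centroid_mz: float
    weight: float
    di: float  # mean deuterons of the binomial component, D units (uncorrected)


@dataclass(frozen=True)
class DeconvolvedPair:
    """Slow/fast population split of one envelope."""

    slow: Component
    fast: Component
    is_bimodal: bool
    model_score: float  # delta-BIC in favor of two components

    @property
    def weights(self) -> tuple[float, float]:
        return self.slow.weight, self.fast.weight


def _component_vector(
    grid: np.ndarray, ref_mz: np.ndarray, ref_int: np.ndarray, d: float, n_exch: int, shift: float
) -> np.ndarray:
    """Binomial-deuterated reference envelope binned onto the fit grid."""
    p = np.clip(d / n_exch, 0.0, 1.0)
    mz, inten = convolve_peak_lists(
        ref_mz, ref_int, np.arange(n_exch + 1) * shift, binomial_weights(n_exch, p)
    )
    vec = np.zeros(grid.size)
    idx = np.clip(np.searchsorted(grid, mz), 0, grid.size - 1)
    left_closer = (idx > 0) & (
        np.abs(mz - grid[np.maximum(idx - 1, 0)]) < np.abs(mz - grid[idx])
    )
    idx[left_closer] -= 1
    np.add.at(vec, idx, inten)
    return vec


def deconvolve_bimodal(
    env: Envelope,
    reference_0: Envelope,
    n_exch: int,
    max_fraction: float = 1.0,
    collapse_tol: float = 0.25,
) -> DeconvolvedPair:
    """Fit a two-population binomial-mixture model to a deuterated envelope.

    Each component is the 0% reference envelope convolved with binomial(N, p)
    deuteration; parameters (weight, mean uptake of each component) come from
    a coarse grid search refined by bounded least squares.  A BIC-style
    comparison against the one-component fit decides bimodality; a degenerate
    two-component fit (components within ``collapse_tol`` D or a vanishing
    weight) is reported as unimodal.
    """
    if env.charge != reference_0.charge or env.peptide_id != reference_0.peptide_id:
        raise ValueError("envelope and 0% reference must share the peptide and charge")
    shift = D_MASS_SHIFT / env.charge
    ref_int = reference_0.intensity / reference_0.total_intensity
    ref_mz = reference_0.mz

    # global fit grid: every position a model component can populate
    grid, _ = convolve_peak_lists(
        ref_mz, ref_int, np.arange(n_exch + 1) * shift, np.ones(n_exch + 1), threshold=0.0
    )
    y = np.zeros(grid.size)
    idx = np.clip(np.searchsorted(grid, env.mz), 0, grid.size - 1)
    left_closer = (idx > 0) & (
        np.abs(env.mz - grid[np.maximum(idx - 1, 0)]) < np.abs(env.mz - grid[idx])
    )
    idx[left_closer] -= 1
    np.add.at(y, idx, env.intensity)
    y = y / y.sum()

    d_max = max_fraction * n_exch
    d_grid = np.linspace(0.0, d_max, 31)
    comps = {d: _component_vector(grid, ref_mz, ref_int, d, n_exch, shift) for d in d_grid}

    # one-component fit
    best1 = min(((float(np.sum((comps[d] - y) ** 2)), d) for d in d_grid), key=lambda r: r[0])

    def resid1(p):
        return _component_vector(grid, ref_mz, ref_int, p[0], n_exch, shift) - y

    sol1 = least_squares(
        resid1, x0=[best1[1]], bounds=([0.0], [d_max]), diff_step=1e-6,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    rss1, d_uni = float(np.sum(sol1.fun**2)), float(sol1.x[0])

    # two-component coarse grid: weight solved in closed form per (d1, d2)
    best2 = None
    for i, d1 in enumerate(d_grid):
        c1 = comps[d1]
        for d2 in d_grid[i + 1 :]:
            c2 = comps[d2]
            diff = c1 - c2
            denom = float(diff @ diff)
            w = 0.5 if denom == 0 else float(np.clip((y - c2) @ diff / denom, 0.0, 1.0))
            rss = float(np.sum((w * c1 + (1 - w) * c2 - y) ** 2))
            if best2 is None or rss < best2[0]:
                best2 = (rss, d1, d2, w)

    def resid2(p):
        d1, d2, w = p
        c1 = _component_vector(grid, ref_mz, ref_int, d1, n_exch, shift)
        c2 = _component_vector(grid, ref_mz, ref_int, d2, n_exch, shift)
        return w * c1 + (1 - w) * c2 - y

    sol2 = least_squares(
        resid2,
        x0=[best2[1], best2[2], best2[3]],
        bounds=([0.0, 0.0, 0.0], [d_max, d_max, 1.0]),
        diff_step=1e-6,
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    rss2 = float(np.sum(sol2.fun**2))
    d1, d2, w1 = (float(v) for v in sol2.x)
    if d1 > d2:
        d1, d2, w1 = d2, d1, 1.0 - w1

    n_obs = y.size
    floor = n_obs * (1e-7) ** 2
    bic1 = n_obs * np.log(max(rss1, floor) / n_obs) + 1 * np.log(n_obs)
    bic2 = n_obs * np.log(max(rss2, floor) / n_obs) + 3 * np.log(n_obs)
    score = float(bic1 - bic2)
    degenerate = (d2 - d1) < collapse_tol or min(w1, 1 - w1) < 1e-3
    is_bimodal = score > BIMODAL_DELTA_BIC and not degenerate

    ref_centroid = float((ref_mz * ref_int).sum())
    if not is_bimodal:
        uni = Component(ref_centroid + d_uni * shift, 1.0, d_uni)
        return DeconvolvedPair(uni, uni, False, score)
    slow = Component(ref_centroid + d1 * shift, w1, d1)
    fast = Component(ref_centroid + d2 * shift, 1.0 - w1, d2)
    return DeconvolvedPair(slow, fast, True, score)


@dataclass(frozen=True)
class AbundanceResult:
    ratio: float  # minor/major weight, in (0, 1]
    time_used: float | None
    fallback: bool  # True when the first time point was not bimodal
    major_is_slow: bool = True


def relative_abundance(pairs: list[tuple[float, DeconvolvedPair]]) -> AbundanceResult:
    """Minor/major population ratio from the earliest bimodal time point.

    The first experimental time point is preferred (centroid separation is
    largest there); if it is unimodal the earliest bimodal point is used and
    flagged.  A series with no bimodal point gets ratio 1 (unimodal peptide).
    """
    if not pairs:
        raise ValueError("no deconvolved time points supplied")
    ordered = sorted(pairs, key=lambda tp: tp[0])
    for i, (t, pair) in enumerate(ordered):
        if pair.is_bimodal:
            w_slow, w_fast = pair.weights
            minor, major = min(w_slow, w_fast), max(w_slow, w_fast)
            return AbundanceResult(minor / major, t, fallback=i > 0, major_is_slow=w_slow >= w_fast)
    return AbundanceResult(1.0, None, fallback=False)


@dataclass(frozen=True)
class TimeCourse:
    """Per-population DI(t) for one peptide, with the population abundance ratio."""

    peptide_id: str
    n_exch: int
    times: np.ndarray  # s
    di_slow: np.ndarray  # D units, back-exchange corrected
    di_fast: np.ndarray
    relative_abundance: float  # minor/major, in (0, 1]
    is_bimodal: bool
    back_exchange_percent: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("times", "di_slow", "di_fast"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
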