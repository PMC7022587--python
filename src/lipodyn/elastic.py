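"""Elastic incoherent neutron scattering analysis.

The elastic intensity of an incoherent scatterer in the Gaussian approximation
is

    I_el(Q) = I0 * exp(-<u^2> Q^2 / 6),

so the hydrogen mean square displacement <u^2> (MSD, A^2) at each temperature
follows from the slope of ln I_el versus Q^2:

    <u^2> = -6 d ln I_el / d Q^2.

The approximation holds up to <u^2> Q^2 ~ 2; points beyond that are flagged
but, matching common practice with a fixed instrument window, retained.

The temperature dependence of the MSD carries the sample resilience: over a
quasi-linear segment the effective force constant (N/m) is

    <k> = 0.00276 / (d<u^2>/dT),

with <u^2> in A^2 and T in K.  Soft matter (steep MSD growth) gives small <k>.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .instruments import InstrumentConfig

__all__ = [
    "ElasticScan",
    "MsdSeries",
    "ForceSegment",
    "ForceSegments",
    "FORCE_CONSTANT_COEFF",
    "GAUSSIAN_VALIDITY_LIMIT",
    "select_q_window",
    "fit_msd",
    "gaussian_validity",
    "bin_ramp",
    "normalize_scan",
    "fit_msd_series",
    "fit_force_constants",
]

#: <k> [N/m] = FORCE_CONSTANT_COEFF / (d<u^2>/dT [A^2/K])
FORCE_CONSTANT_COEFF = 0.00276

#: The Gaussian approximation is taken to hold up to <u^2> Q^2 of this value.
GAUSSIAN_VALIDITY_LIMIT = 2.0


@dataclass(frozen=True)
class ElasticScan:
    """Elastic intensities I(Q) at one temperature, with 1-sigma uncertainties."""

    temperature: float  # K
    q: np.ndarray  # 1/Angstrom
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if not (q.shape == i.shape == s.shape):
            raise ValueError("q, intensity and sigma must have matching shapes")
        if q.size and np.any(q <= 0):
            raise ValueError("Q values must be positive")
        if s.size and np.any(s < 0):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class MsdSeries:
    """Fitted MSD versus temperature."""

    temperature: np.ndarray  # K, strictly increasing
    msd: np.ndarray  # A^2
    msd_sigma: np.ndarray  # A^2
    valid_fraction: np.ndarray  # fraction of points with <u^2> Q^2 <= 2

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        for name in ("temperature", "msd", "msd_sigma", "valid_fraction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return self.temperature.size


@dataclass(frozen=True)
class ForceSegment:
    t_low: float
    t_high: float
    slope: float  # A^2/K
    slope_stderr: float
    force_constant: float | None  # N/m; None when the segment is rigid/undefined
    stderr: float | None
    flag: str = ""


@dataclass(frozen=True)
class ForceSegments:
    segments: tuple[ForceSegment, ...]

    @property
    def force_constants(self) -> list[float | None]:
        return [s.force_constant for s in self.segments]


def select_q_window(scan: ElasticScan, cfg: InstrumentConfig) -> ElasticScan:
    """Retain only points inside the instrument's usable Q window."""
    if len(scan) == 0:
        raise ValueError("scan is empty")
    qmin, qmax = cfg.q_window
    keep = (scan.q >= qmin) & (scan.q <= qmax)
    if keep.sum() < 3:
        raise ValueError(
            f"window too narrow: {int(keep.sum())} point(s) survive in "
            f"[{qmin}, {qmax}] 1/A; at least 3 required"
        )
    return ElasticScan(scan.temperature, scan.q[keep], scan.intensity[keep], scan.sigma[keep])


def _weighted_linfit(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted least squares y = a + b x.

    Returns (a, b, var_a, var_b).  With w = None an unweighted fit is done and
    the parameter variances are scaled by the residual variance; with explicit
    weights (1/sigma_y^2) the covariance is the standard propagated one.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("singular design: all abscissae are equal")
    scaled = w is None
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    b = (w * (x - xbar) * (y - ybar)).sum() / sxx
    a = ybar - b * xbar
    var_b = 1.0 / sxx
    var_a = 1.0 / sw + xbar**2 / sxx
    if scaled:
        dof = max(n - 2, 1)
        s2 = (w * (y - a - b * x) ** 2).sum() / dof
        var_a *= s2
        var_b *= s2
    return a, b, var_a, var_b


def fit_msd(scan: ElasticScan) -> tuple[float, float]:
    """MSD (A^2) and its 1-sigma uncertainty from one windowed elastic scan.

    Weighted least squares of ln(intensity) on Q^2; the MSD is -6x the slope.
    Weights are 1/sigma_lnI^2 with sigma_lnI = sigma/I; if every sigma is zero
    (noise-free synthetic data) the fit is unweighted and exact.
    """
    if len(scan) < 3:
        raise ValueError("at least 3 points are required to fit the MSD")
    if np.any(scan.intensity <= 0):
        raise ValueError("all intensities must be positive to take the logarithm")
    x = scan.q**2
    y = np.log(scan.intensity)
    if np.all(scan.sigma == 0):
        w = None
    else:
        sig_ln = np.where(scan.sigma > 0, scan.sigma / scan.intensity, np.inf)
        w = 1.0 / sig_ln**2
        if not np.any(np.isfinite(sig_ln)):
            w = None
    _, slope, _, var_b = _weighted_linfit(x, y, w)
    return -6.0 * slope, 6.0 * float(np.sqrt(var_b))


def gaussian_validity(msd: float, scan: ElasticScan) -> tuple[np.ndarray, float]:
    """Per-point mask of <u^2> Q^2 <= 2 and the valid fraction.

    Warn-only policy: the fixed Q window is retained even where the Gaussian
    approximation degrades; callers get the mask to apply stricter policies.
    """
    if msd < 0:
        raise ValueError("msd must be non-negative")
    mask = msd * scan.q**2 <= GAUSSIAN_VALIDITY_LIMIT
    frac = float(mask.mean()) if len(scan) else 1.0
    if frac < 1.0:
        warnings.warn(
            f"Gaussian approximation exceeded (<u^2>Q^2 > {GAUSSIAN_VALIDITY_LIMIT}) "
            f"for {(~mask).sum()} of {len(scan)} points at T={scan.temperature} K",
            stacklevel=2,
        )
    return mask, frac


def bin_ramp(scans: list[ElasticScan], bin_width: float) -> list[ElasticScan]:
    """Bin ramp scans to temperature intervals of ``bin_width`` K.

    Bins are [T0 + n*w, T0 + (n+1)*w) anchored at the lowest scan temperature;
    intensities are averaged per Q point and uncertainties combined in
    quadrature / n; the bin center is reported as the temperature.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not scans:
        raise ValueError("no scans to bin")
    t0 = min(s.temperature for s in scans)
    groups: dict[int, list[ElasticScan]] = {}
    for s in scans:
        groups.setdefault(int(np.floor((s.temperature - t0) / bin_width)), []).append(s)
    out = []
    for idx in sorted(groups):
        members = groups[idx]
        q = members[0].q
        for m in members[1:]:
            if not np.array_equal(m.q, q):
                raise ValueError("scans in one temperature bin must share the Q grid")
        n = len(members)
        inten = np.mean([m.intensity for m in members], axis=0)
        sig = np.sqrt(np.sum([m.sigma**2 for m in members], axis=0)) / n
        out.append(ElasticScan(t0 + (idx + 0.5) * bin_width, q, inten, sig))
    return out


def normalize_scan(
    scan: ElasticScan,
    empty_cell: ElasticScan | None = None,
    vanadium: ElasticScan | None = None,
    transmission: float = 1.0,
) -> ElasticScan:
    """Empty-cell subtraction, scalar transmission and vanadium normalization.

    I' = (I - I_empty) / transmission / I_vanadium, point-wise on a shared Q
    grid; absorption is treated as the scalar ``transmission`` (full
    Paalman-Pings coefficients are out of scope).  Uncertainties propagate in
    first order.
    """
    if transmission <= 0:
        raise ValueError("transmission must be positive")
    for ref, label in ((empty_cell, "empty_cell"), (vanadium, "vanadium")):
        if ref is not None and not np.array_equal(ref.q, scan.q):
            raise ValueError(f"{label} scan must share the Q grid of the sample scan")
    inten = scan.intensity.copy()
    var = scan.sigma**2
    if empty_cell is not None:
        inten = inten - empty_cell.intensity
        var = var + empty_cell.sigma**2
    inten = inten / transmission
    var = var / transmission**2
    if vanadium is not None:
        if np.any(vanadium.intensity == 0):
            raise ValueError("vanadium intensity is zero at one or more Q points")
        var = var / vanadium.intensity**2 + (inten**2 / vanadium.intensity**4) * vanadium.sigma**2
        inten = inten / vanadium.intensity
    return ElasticScan(scan.temperature, scan.q, inten, np.sqrt(var))


def fit_msd_series(scans: list[ElasticScan], cfg: InstrumentConfig | None = None) -> MsdSeries:
    """Window (optionally), fit the MSD of every scan and assemble the series."""
    rows = []
    for scan in sorted(scans, key=lambda s: s.temperature):
        if cfg is not None:
            scan = select_q_window(scan, cfg)
        msd, sig = fit_msd(scan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, frac = gaussian_validity(max(msd, 0.0), scan)
        rows.append((scan.temperature, msd, sig, frac))
    t, m, s, f = (np.array(col) for col in zip(*rows))
    return MsdSeries(t, m, s, f)


def fit_force_constants(
    series: MsdSeries, breakpoints: tuple[float, ...] = (200.0, 250.0)
) -> ForceSegments:
    """Per-segment weighted linear fits of MSD vs T; <k> = 0.00276 / slope.

    ``breakpoints`` split the temperature range into contiguous segments;
    a point exactly at a breakpoint belongs to both adjacent segments (the
    model is continuous there).  Segments with non-positive slope are flagged
    "rigid/undefined" and carry no force constant.
    """
    bps = sorted(breakpoints)
    tmin, tmax = series.temperature.min(), series.temperature.max()
    if any(not (tmin < b < tmax) for b in bps):
        raise ValueError(f"breakpoints {bps} must lie inside ({tmin}, {tmax})")
    edges = [tmin, *bps, tmax]
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (series.temperature >= lo) & (series.temperature <= hi)
        if sel.sum() < 2:
            raise ValueError(f"segment [{lo}, {hi}] K has fewer than 2 MSD points")
        x = series.temperature[sel]
        y = series.msd[sel]
        sig = series.msd_sigma[sel]
        w = None if np.all(sig == 0) else 1.0 / np.where(sig > 0, sig, np.inf) ** 2
        _, slope, _, var_b = _weighted_linfit(x, y, w)
        serr = float(np.sqrt(var_b))
        if slope <= 0:
            segments.append(ForceSegment(lo, hi, slope, serr, None, None, "rigid/undefined"))
        else:
            k = FORCE_CONSTANT_COEFF / slope
            segments.append(ForceSegment(lo, hi, slope, serr, k, k * serr / slope))
    return ForceSegments(tuple(segments))
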