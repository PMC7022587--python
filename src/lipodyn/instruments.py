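"""Backscattering-spectrometer configurations for elastic temperature scans.

An :class:`InstrumentConfig` bundles everything the elastic-scan simulator and
the momentum-transfer windowing need: the usable Q window, the detector Q grid,
the (metadata-only) energy resolution, and the temperature protocol — either a
stepped list of set points or a continuous ramp that is later binned.

Two presets mirror typical thermal ("IN13-like", ~8 µeV, stepped scan) and
cold ("IN16-like", ~0.9 µeV, 0.3 K/min ramp) neutron backscattering setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["InstrumentConfig", "RampProtocol", "IN13_LIKE", "IN16_LIKE", "get_instrument"]


@dataclass(frozen=True)
class RampProtocol:
    """Continuous temperature ramp, sampled at a fixed rate and binned later.

    rate_K_per_min: ramp speed; one sample is drawn per minute of ramp, i.e.
    every ``rate_K_per_min`` kelvin. bin_width_K is the downstream bin size.
    """

    t_start: float
    t_stop: float
    rate_K_per_min: float = 0.3
    bin_width_K: float = 5.0

    def sample_temperatures(self) -> np.ndarray:
        # one sample per minute at the stated ramp rate; stop is exclusive
        return np.arange(self.t_start, self.t_stop, self.rate_K_per_min)


@dataclass(frozen=True)
class InstrumentConfig:
    name: str
    q_window: tuple[float, float]  # (Qmin, Qmax), 1/Angstrom
    q_grid: tuple[float, ...]  # ordered detector Q values, 1/Angstrom
    energy_resolution_ueV: float  # metadata only
    temperatures: tuple[float, ...] = ()  # stepped protocol, K
    ramp: RampProtocol | None = None

    def __post_init__(self) -> None:
        qmin, qmax = self.q_window
        if not qmin < qmax:
            raise ValueError(f"q_window must satisfy Qmin < Qmax, got {self.q_window}")
        grid = np.asarray(self.q_grid, dtype=float)
        if grid.size and np.any(np.diff(grid) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        if grid.size and (grid.min() < qmin or grid.max() > qmax):
            raise ValueError("q_grid points must lie within the q_window")

    def protocol_temperatures(self) -> np.ndarray:
        """Temperatures at which elastic scans are recorded, in K."""
        if self.ramp is not None:
            return self.ramp.sample_temperatures()
        return np.asarray(self.temperatures, dtype=float)


def _stepped(*segments: tuple[float, float, float]) -> tuple[float, ...]:
    temps: list[float] = []
    for lo, hi, step in segments:
        temps.extend(np.arange(lo, hi + step / 2, step))
    return tuple(float(t) for t in temps)


#: Thermal backscattering preset: 0.52 < Q < 2.06 1/A, ~8 ueV, stepped scan
#: 20-160 K by 20 K, 170-280 K by 10 K, 285-305 K by 5 K.
IN13_LIKE = InstrumentConfig(
    name="IN13-like",
    q_window=(0.52, 2.06),
    q_grid=tuple(np.round(np.linspace(0.55, 2.05, 16), 4)),
    energy_resolution_ueV=8.0,
    temperatures=_stepped((20, 160, 20), (170, 280, 10), (285, 305, 5)),
)

#: Cold backscattering preset: 0.54 < Q < 1.85 1/A, ~0.9 ueV, 0.3 K/min ramp
#: over 20-310 K binned to 5 K downstream.
IN16_LIKE = InstrumentConfig(
    name="IN16-like",
    q_window=(0.54, 1.85),
    q_grid=tuple(np.round(np.linspace(0.56, 1.84, 16), 4)),
    energy_resolution_ueV=0.9,
    ramp=RampProtocol(t_start=20.0, t_stop=310.0, rate_K_per_min=0.3, bin_width_K=5.0),
)

_PRESETS = {"IN13-like": IN13_LIKE, "IN16-like": IN16_LIKE}


def get_instrument(name: str) -> InstrumentConfig:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown instrument preset {name!r}; known: {sorted(_PRESETS)}") from None
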