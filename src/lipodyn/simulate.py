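"""Synthetic elastic scans and HDX-MS datasets with known ground truth.

The generators emulate the two experiments the analysis modules target:

* **Elastic temperature scans** under the Gaussian approximation with a
  piecewise-linear MSD(T) (three quasi-linear regimes changing slope near
  200 K and 250 K) and counting-statistics-like Gaussian noise.

* **HDX-MS time courses** at pD 7.2, 0 degC over {30, 100, 300, 1000, 3000,
  10000} s: per-residue deuteration probabilities from the random-coil rates
  divided by ground-truth protection factors, one- or two-population (bimodal)
  mixtures at stated abundance ratios, isotopic fine structure from residue
  elemental compositions, uniform back exchange, and 0% / 80% controls.

Everything is seeded and byte-reproducible, so every downstream stage has a
recoverable target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

from .elastic import ElasticScan, FORCE_CONSTANT_COEFF
from .envelope import TIME_CONTROL_0, TIME_CONTROL_80, Envelope
from .instruments import InstrumentConfig
from .intrinsic import ExchangeConditions, intrinsic_rates
from .isotopes import (
    D_MASS_SHIFT,
    convolve_peak_lists,
    merge_peaks,
    natural_isotope_peaks,
    poisson_binomial,
    to_mz,
)
from .peptides import DEFAULT_N_TERM_EXCLUDED, PeptideRecord, exchangeable_positions

__all__ = [
    "MsdModel",
    "HdxTruth",
    "PAPER_TIMES",
    "apoa1_sequence",
    "make_elastic_dataset",
    "digest_protein",
    "make_hdx_dataset",
    "default_charge_policy",
]

#: HDX sampling times used throughout (seconds)
PAPER_TIMES = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)


def apoa1_sequence() -> str:
    """The packaged 243-residue mature human apoA-I test sequence."""
    text = resources.files("lipodyn.data").joinpath("apoa1_mature.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@dataclass(frozen=True)
class MsdModel:
    """Continuous piecewise-linear MSD(T), parameterized by force constants.

    Segment slopes are 0.00276 / <k>_i (A^2/K), so soft regimes (small force
    constant) grow fast.  The curve is anchored at (t_anchor, msd_at_anchor).
    """

    breakpoints: tuple[float, ...] = (200.0, 250.0)
    segment_force_constants: tuple[float, ...] = (1.0, 0.25, 0.15)
    msd_at_anchor: float = 0.05  # A^2
    t_anchor: float = 20.0  # K

    def __post_init__(self) -> None:
        if len(self.segment_force_constants) != len(self.breakpoints) + 1:
            raise ValueError("need one force constant per segment (breakpoints + 1)")
        if any(k <= 0 for k in self.segment_force_constants):
            raise ValueError("force constants must be positive")
        if sorted(self.breakpoints) != list(self.breakpoints):
            raise ValueError("breakpoints must be increasing")

    @property
    def slopes(self) -> tuple[float, ...]:
        return tuple(FORCE_CONSTANT_COEFF / k for k in self.segment_force_constants)

    def msd(self, temperature: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(temperature, dtype=float))
        out = np.full(t.shape, self.msd_at_anchor)
        prev = self.t_anchor
        for i, slope in enumerate(self.slopes):
            hi = self.breakpoints[i] if i < len(self.breakpoints) else np.inf
            out += slope * np.clip(t - prev, 0.0, hi - prev)
            prev = hi
        out += self.slopes[0] * np.minimum(t - self.t_anchor, 0.0)  # extrapolate below anchor
        return out


def make_elastic_dataset(
    cfg: InstrumentConfig,
    model: MsdModel,
    i0: float = 1.0,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[ElasticScan], np.ndarray, np.ndarray]:
    """Generate one elastic scan per protocol temperature.

    I(Q, T) = i0 * exp(-msd(T) * Q^2 / 6) plus Gaussian noise with
    sigma = noise_fraction * sqrt(I / I_max) per point; the same sigma is
    recorded as the point uncertainty.  Returns (scans, temperatures,
    ground-truth MSD values).
    """
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    temps = cfg.protocol_temperatures()
    if temps.size == 0:
        raise ValueError(f"instrument {cfg.name!r} has an empty temperature protocol")
    rng = np.random.default_rng(seed)
    q = np.asarray(cfg.q_grid, dtype=float)
    truth = model.msd(temps)
    scans = []
    for t, u2 in zip(temps, truth):
        inten = i0 * np.exp(-u2 * q**2 / 6.0)
        sigma = noise_fraction * np.sqrt(inten / i0)
        if noise_fraction > 0:
            inten = inten + rng.normal(0.0, 1.0, q.size) * sigma
        scans.append(ElasticScan(float(t), q, inten, sigma))
    return scans, temps, truth


def digest_protein(
    sequence: str,
    mean_length: int = 12,
    coverage_target: int = 150,
    seed: int = 0,
    min_length: int = 5,
) -> list[PeptideRecord]:
    """Emulate proteolytic digestion as a set of overlapping residue spans.

    A deterministic (seeded) two-pass scheme: a tiling pass guarantees >= 95%
    sequence coverage, then random overlapping spans are added until
    ``coverage_target`` peptides exist.  The cut-site model is generic
    plumbing, not a protease model.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    if mean_length < 4:
        raise ValueError("mean_length must be >= 4")
    n = len(sequence)
    rng = np.random.default_rng(seed)
    if mean_length >= n:
        if coverage_target > 1:
            warnings.warn("sequence shorter than mean_length: returning a single span")
        return [PeptideRecord(sequence, 1, n)]

    spans: set[tuple[int, int]] = set()
    # tiling pass with ~50% overlap
    step = max(mean_length // 2, 1)
    start = 1
    while start <= n:
        length = int(np.clip(round(rng.normal(mean_length, mean_length / 4)), min_length, n))
        end = min(start + length - 1, n)
        if end - start + 1 < min(min_length, n):
            start = n - min(mean_length, n) + 1
            end = n
        spans.add((start, end))
        if end == n:
            break
        start += step
    # random overlapping spans
    attempts = 0
    while len(spans) < coverage_target and attempts < 50 * coverage_target:
        attempts += 1
        length = int(np.clip(round(rng.normal(mean_length, mean_length / 3)), min_length, n))
        start = int(rng.integers(1, n - length + 2))
        spans.add((start, start + length - 1))
    if len(spans) < coverage_target:
        warnings.warn(
            f"coverage target {coverage_target} unreachable; produced {len(spans)} spans"
        )
    return [PeptideRecord(sequence[s - 1 : e], s, e) for s, e in sorted(spans)]


def default_charge_policy(peptide: PeptideRecord) -> int:
    """2+ for short peptides, 3+ from 16 residues on (typical ion-trap HDX)."""
    return 2 if len(peptide) < 16 else 3


@dataclass(frozen=True)
class HdxTruth:
    """Ground truth for a synthetic HDX-MS experiment.

    per_pool_pf maps a pool label ("dimer", "monomer") to a full-length
    per-residue protection-factor array (NaN where undefined, e.g. prolines);
    mixture_weights gives the population weight of each pool (summing to 1).
    A peptide is bimodal whenever its residues' Pf differ between pools.
    """

    sequence: str
    peptides: tuple[PeptideRecord, ...]
    per_pool_pf: Mapping[str, np.ndarray]
    mixture_weights: Mapping[str, float]
    conditions: ExchangeConditions = ExchangeConditions()
    times: tuple[float, ...] = PAPER_TIMES
    back_exchange_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_weights.values()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if list(self.times) != sorted(self.times) or len(set(self.times)) != len(self.times):
            raise ValueError("times must be strictly increasing")
        for pool, pf in self.per_pool_pf.items():
            pf = np.asarray(pf, dtype=float)
            if pf.size != len(self.sequence):
                raise ValueError(f"pool {pool!r}: Pf array must cover the full sequence")
            if np.any(pf[np.isfinite(pf)] < 1.0):
                raise ValueError(f"pool {pool!r}: protection factors must be >= 1")
            object.__setattr__(
                self, "per_pool_pf", {**self.per_pool_pf, pool: pf}
            )
        for pep in self.peptides:
            if pep.end > len(self.sequence) or pep.start < 1:
                raise ValueError(f"peptide {pep.peptide_id} outside the sequence")
            if self.sequence[pep.start - 1 : pep.end] != pep.sequence:
                raise ValueError(f"peptide {pep.peptide_id} does not match the sequence")

    def site_probabilities(
        self, peptide: PeptideRecord, pool: str, time: float, back_exchange: bool = True
    ) -> np.ndarray:
        """Per-exchangeable-site deuteration probability at one time."""
        prof = intrinsic_rates(peptide, self.conditions)
        pf = self.per_pool_pf[pool]
        probs = []
        for pos in prof.positions:
            global_idx = peptide.start + pos - 2  # 0-based index into sequence
            pf_i = pf[global_idx]
            if not np.isfinite(pf_i):
                res = peptide.sequence[pos - 1]
                raise ValueError(
                    f"no protection factor for residue {res}{peptide.start + pos - 1} "
                    f"(pool {pool!r}) covered by peptide {peptide.peptide_id}"
                )
            probs.append(1.0 - np.exp(-prof.rates[pos] / pf_i * time))
        p = self.conditions.d2o_fraction * np.asarray(probs)
        if back_exchange:
            p = p * (1.0 - self.back_exchange_fraction)
        return p

    def expected_di(
        self, peptide: PeptideRecord, pool: str, times: Sequence[float] | None = None
    ) -> np.ndarray:
        """Ground-truth DI(t) of one population, before back exchange."""
        ts = self.times if times is None else times
        return np.array(
            [self.site_probabilities(peptide, pool, t, back_exchange=False).sum() for t in ts]
        )


def make_reference_envelope(peptide: PeptideRecord, charge: int | None = None) -> Envelope:
    """Noise-free 0% (natural-abundance) envelope of a peptide."""
    z = charge or default_charge_policy(peptide)
    nat_mass, nat_int = natural_isotope_peaks(peptide.sequence)
    return Envelope(peptide.peptide_id, z, TIME_CONTROL_0, to_mz(nat_mass, z), nat_int)


def make_two_population_envelope(
    peptide: PeptideRecord,
    di_slow: float,
    di_fast: float,
    weight_slow: float,
    time: float = 30.0,
    charge: int | None = None,
    noise_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[Envelope, Envelope]:
    """Mixture envelope of two populations at stated mean uptakes and weights.

    Each population is the natural envelope convolved with a binomial
    deuteration distribution of the stated mean (uniform per-site
    probability).  Returns (mixture envelope, 0% reference envelope) — the
    direct construction for deconvolution studies where the population DI
    separation and abundance ratio are the controlled variables.
    """
    from .isotopes import binomial_weights

    z = charge or default_charge_policy(peptide)
    n_sites = len(exchangeable_positions(peptide))
    if not 0 <= di_slow <= n_sites and 0 <= di_fast <= n_sites:
        raise ValueError("population uptakes must lie in [0, n_exch]")
    nat_mass, nat_int = natural_isotope_peaks(peptide.sequence)
    nat_mz = to_mz(nat_mass, z)
    shifts = np.arange(n_sites + 1) * (D_MASS_SHIFT / z)
    mix_mz, mix_int = None, None
    for di, w in ((di_slow, weight_slow), (di_fast, 1.0 - weight_slow)):
        mz_p, int_p = convolve_peak_lists(
            nat_mz, nat_int, shifts, binomial_weights(n_sites, di / n_sites)
        )
        if mix_mz is None:
            mix_mz, mix_int = mz_p, w * int_p
        else:
            mix_mz, mix_int = merge_peaks(
                np.concatenate([mix_mz, mz_p]), np.concatenate([mix_int, w * int_p])
            )
    mix_int = mix_int / mix_int.sum()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_fraction * mix_int.max() * np.sqrt(mix_int / mix_int.max())
        mix_int = np.clip(mix_int + rng.normal(0.0, 1.0, mix_int.size) * sigma, 0.0, None)
    env = Envelope(peptide.peptide_id, z, time, mix_mz, mix_int)
    return env, Envelope(peptide.peptide_id, z, TIME_CONTROL_0, nat_mz, nat_int)


def _deuterated_envelope(
    nat_mz: np.ndarray, nat_int: np.ndarray, site_probs: np.ndarray, charge: int
) -> tuple[np.ndarray, np.ndarray]:
    weights = poisson_binomial(site_probs)
    shifts = np.arange(weights.size) * (D_MASS_SHIFT / charge)
    return convolve_peak_lists(nat_mz, nat_int, shifts, weights)


def make_hdx_dataset(
    truth: HdxTruth,
    charge_policy: Callable[[PeptideRecord], int] | None = None,
    noise_fraction: float = 0.0,
    control_fraction: float = 0.8,
) -> list[Envelope]:
    """Generate per-peptide, per-time envelopes plus 0% and 80% controls.

    Each peptide's envelope at time t is the mixture-weight sum of its pool
    envelopes; each pool's deuteration is sampled per residue from the
    random-coil rate divided by that pool's protection factor.  Back exchange
    removes a uniform fraction of incorporated D (controls included, as in a
    real workflow).  Envelope intensities are normalized to total 1 before
    seeded Gaussian noise (sigma = noise_fraction * sqrt(I / I_max)) is added.
    """
    policy = charge_policy or default_charge_policy
    rng = np.random.default_rng(truth.seed)
    out: list[Envelope] = []
    for pep in truth.peptides:
        z = policy(pep)
        nat_mass, nat_int = natural_isotope_peaks(pep.sequence)
        nat_mz = to_mz(nat_mass, z)
        n_sites = len(exchangeable_positions(pep))

        def emit(time: float, mz: np.ndarray, inten: np.ndarray) -> None:
            inten = inten / inten.sum()
            if noise_fraction > 0:
                # counting-like: sigma relative to the base peak, sqrt-scaled per peak
                sigma = noise_fraction * inten.max() * np.sqrt(inten / inten.max())
                inten = np.clip(inten + rng.normal(0.0, 1.0, inten.size) * sigma, 0.0, None)
            out.append(Envelope(pep.peptide_id, z, time, mz, inten))

        emit(TIME_CONTROL_0, nat_mz, nat_int.copy())
        p80 = np.full(n_sites, control_fraction * (1.0 - truth.back_exchange_fraction))
        emit(TIME_CONTROL_80, *_deuterated_envelope(nat_mz, nat_int, p80, z))
        for t in truth.times:
            mix_mz, mix_int = None, None
            for pool, weight in truth.mixture_weights.items():
                probs = truth.site_probabilities(pep, pool, t)
                mz_p, int_p = _deuterated_envelope(nat_mz, nat_int, probs, z)
                if mix_mz is None:
                    mix_mz, mix_int = mz_p, weight * int_p
                else:
                    mix_mz, mix_int = merge_peaks(
                        np.concatenate([mix_mz, mz_p]),
                        np.concatenate([mix_int, weight * int_p]),
                    )
            emit(t, mix_mz, mix_int)
    return out
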