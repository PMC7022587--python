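"""Random-coil (intrinsic) backbone amide H->D exchange rates.

The intrinsic exchange rate of the amide of residue *i* in an unstructured
chain combines acid-, base- and water-catalyzed channels,

    k_rc(i) = k_A * [D+] * 10^(A_own(i) + A_next(i-1))
            + (k_B * [OD-] + k_W) * 10^(B_own(i) + B_next(i-1)),

with [D+] = 10^-pD, [OD-] = 10^(pD - pK_D2O(T)), side-chain factors of the
residue itself ("own") and of its left neighbor ("next", i.e. the neighbor's
effect on the following amide), free-terminus corrections, and per-channel
Arrhenius scaling from the 20 degC reference temperature.  The calibration
constants live in a versioned YAML data file (``data/rc_rate_constants.yaml``)
and can be swapped via :func:`load_rate_constants`.

Titratable side chains (Asp, Glu, His) and the C-terminal carboxyl mix their
protonated/deprotonated factors through the Henderson-Hasselbalch ratio at the
working pD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

from .fitting import fit_single_stretched
from .peptides import DEFAULT_N_TERM_EXCLUDED, PeptideRecord, exchangeable_positions

__all__ = [
    "ExchangeConditions",
    "IntrinsicRateProfile",
    "load_rate_constants",
    "intrinsic_rates",
    "random_coil_curve",
    "average_rc_rate",
    "completion_time",
]

R_CAL = 1.987204e-3  # gas constant, kcal/(mol K)


@dataclass(frozen=True)
class ExchangeConditions:
    """Labeling conditions.  pD is the direct meter reading + 0.4."""

    pD: float = 7.2
    temperature: float = 273.15  # K
    pD_quench: float = 2.4  # metadata; quench kinetics are out of scope
    d2o_fraction: float = 1.0  # deuterium fraction of the labeling buffer

    def __post_init__(self) -> None:
        if not 0 < self.pD < 14:
            raise ValueError("pD out of range (0, 14)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not 0 < self.d2o_fraction <= 1:
            raise ValueError("d2o_fraction must be in (0, 1]")


@dataclass(frozen=True)
class IntrinsicRateProfile:
    """Per-residue intrinsic rates (1/s), absent for prolines and excluded N-term."""

    peptide: PeptideRecord
    conditions: ExchangeConditions
    rates: Mapping[int, float]  # 1-based peptide position -> k_rc (1/s)

    @property
    def positions(self) -> list[int]:
        return sorted(self.rates)

    def rate_array(self) -> np.ndarray:
        return np.array([self.rates[p] for p in self.positions])

    def scaled(self, factor: float) -> "IntrinsicRateProfile":
        """Uniformly rescale every rate (e.g. divide by a protection factor)."""
        return IntrinsicRateProfile(
            self.peptide, self.conditions, {p: k * factor for p, k in self.rates.items()}
        )


def load_rate_constants(path: str | None = None) -> dict:
    """Load the exchange calibration table (packaged file by default)."""
    if path is None:
        text = resources.files("lipodyn.data").joinpath("rc_rate_constants.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def _titrate(f_prot: float, f_deprot: float, pKa: float, pD: float) -> float:
    """Log-factor of a titratable group: population-weighted rate contribution."""
    frac_prot = 1.0 / (1.0 + 10.0 ** (pD - pKa))
    return float(np.log10(frac_prot * 10.0**f_prot + (1 - frac_prot) * 10.0**f_deprot))


def _factor(table: dict, aa: str, role: str, channel: str, pD: float) -> float:
    """Side-chain factor of residue ``aa`` in role 'own'/'next' for 'acid'/'base'."""
    entry = table["residues"][aa]
    key = f"{channel}_{role}"
    if aa in table.get("side_chain_pKa_D2O", {}) and "protonated" in entry:
        pKa = table["side_chain_pKa_D2O"][aa]
        return _titrate(entry["protonated"][key], entry["deprotonated"][key], pKa, pD)
    val = entry[key]
    if val is None:
        raise ValueError(f"residue {aa} has no {key} factor (no backbone amide)")
    return float(val)


def _arrhenius(ea_kcal: float, temperature: float, t_ref: float) -> float:
    return float(np.exp(-ea_kcal / R_CAL * (1.0 / temperature - 1.0 / t_ref)))


def intrinsic_rates(
    peptide: PeptideRecord | str,
    cond: ExchangeConditions,
    constants: dict | None = None,
    n_term_excluded: int = DEFAULT_N_TERM_EXCLUDED,
    free_termini: bool = True,
) -> IntrinsicRateProfile:
    """Per-residue random-coil exchange rates (1/s) for one peptide.

    ``free_termini`` applies the free alpha-amine / carboxylate corrections,
    appropriate for a digested peptide measured in isolation.
    """
    if isinstance(peptide, str):
        peptide = PeptideRecord(peptide, 1, len(peptide))
    tab = constants if constants is not None else load_rate_constants()
    ref = tab["reference_rates"]
    ea = tab["activation_energies_kcal_per_mol"]
    t_ref = float(ref["T_ref_K"])
    T, pD = cond.temperature, cond.pD

    pkd_ref = tab["pK_D2O"]["value_at_T_ref"]
    dh = tab["pK_D2O"]["delta_H_kcal_per_mol"]
    pKD = pkd_ref + dh / (R_CAL * np.log(10.0)) * (1.0 / T - 1.0 / t_ref)

    k_acid_ref = 10.0 ** ref["log_k_acid"] * _arrhenius(ea["acid"], T, t_ref)
    k_base_ref = 10.0 ** ref["log_k_base"] * _arrhenius(ea["base"], T, t_ref)
    k_water_ref = 10.0 ** ref["log_k_water"] * _arrhenius(ea["water"], T, t_ref)
    d_conc = 10.0**-pD
    od_conc = 10.0 ** (pD - pKD)

    seq = peptide.sequence
    rates: dict[int, float] = {}
    for pos in exchangeable_positions(peptide, n_term_excluded):
        if pos == 1:
            continue  # residue 1 carries the free amine, not an amide
        aa, left = seq[pos - 1], seq[pos - 2]
        fa = _factor(tab, aa, "own", "acid", pD) + _factor(tab, left, "next", "acid", pD)
        fb = _factor(tab, aa, "own", "base", pD) + _factor(tab, left, "next", "base", pD)
        if free_termini and pos == 2:
            fa += tab["termini"]["N_term"]["acid_next"]
            fb += tab["termini"]["N_term"]["base_next"]
        if free_termini and pos == len(seq):
            pKa_ct = tab["side_chain_pKa_D2O"]["C_term"]
            fa += _titrate(
                tab["termini"]["C_term_protonated"]["acid_own"],
                tab["termini"]["C_term_deprotonated"]["acid_own"],
                pKa_ct,
                pD,
            )
            fb += _titrate(
                tab["termini"]["C_term_protonated"]["base_own"],
                tab["termini"]["C_term_deprotonated"]["base_own"],
                pKa_ct,
                pD,
            )
        k_per_min = k_acid_ref * d_conc * 10.0**fa + (k_base_ref * od_conc + k_water_ref) * 10.0**fb
        rates[pos] = k_per_min / 60.0
    return IntrinsicRateProfile(peptide, cond, rates)


def random_coil_curve(
    profile: IntrinsicRateProfile, times: np.ndarray, pf: Mapping[int, float] | float = 1.0
) -> np.ndarray:
    """Deuterium incorporation DI(t) = d2o_fraction * sum_i (1 - exp(-k_i t / Pf_i)).

    ``pf`` optionally slows residues by per-position (or uniform) protection
    factors; the default 1.0 is the random-coil reference curve.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    di = np.zeros_like(t)
    for pos, k in profile.rates.items():
        p = pf if np.isscalar(pf) else pf[pos]
        di += 1.0 - np.exp(-(k / p) * t)
    return profile.conditions.d2o_fraction * di


def completion_time(profile: IntrinsicRateProfile, fraction: float, pf: float = 1.0) -> float:
    """Time at which the average completion DI(t)/N reaches ``fraction``.

    Solved in log10-time so the answer is exactly equivariant under a uniform
    rescaling of all rates.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(profile.rates)
    if n == 0:
        raise ValueError("profile has no exchangeable residues")
    dfrac = profile.conditions.d2o_fraction

    def g(logt: float) -> float:
        return random_coil_curve(profile, np.array([10.0**logt]), pf)[0] / (dfrac * n) - fraction

    lo, hi = -15.0, 15.0
    return 10.0 ** brentq(g, lo, hi, xtol=1e-13, rtol=8.9e-16)


def adaptive_time_grid(profile: IntrinsicRateProfile, n_points: int = 30) -> np.ndarray:
    """Log-spaced grid between the 1% and 99% average-completion times."""
    t1 = completion_time(profile, 0.01)
    t99 = completion_time(profile, 0.99)
    return np.logspace(np.log10(t1), np.log10(t99), n_points)


def average_rc_rate(
    profile: IntrinsicRateProfile, time_grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Average exchange rate and heterogeneity of a rate distribution.

    Fits DI(t) = N * (1 - exp(-(k t)^beta)) with 0 < beta <= 1 on the given
    grid (default: the adaptive 30-point log grid spanning 1%-99% completion,
    which makes the fitted k exactly scale-equivariant).  Returns (k_avg 1/s,
    beta).
    """
    if time_grid is None:
        time_grid = adaptive_time_grid(profile)
    t = np.asarray(time_grid, dtype=float)
    di = random_coil_curve(profile, t)
    n = profile.conditions.d2o_fraction * len(profile.rates)
    k, beta, _ = fit_single_stretched(t, di, n)
    return k, beta
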