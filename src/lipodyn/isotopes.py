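"""Aggregated isotopic fine structure for peptides and their deuterated forms.

Elemental compositions come from pyteomics' standard residue table; the
aggregated (unit-resolution) isotope pattern is computed by multinomial
expansion — per-element single-atom distributions over the extra-neutron
index, raised to the atom count by exponentiation-by-squaring, tracking the
intensity-weighted mean mass of every aggregated peak.  Peaks below a relative
abundance threshold (default 1e-4) are dropped.

Deuteration adds +1.006277 Da per incorporated D; the number of D across
exchangeable sites with per-site probabilities p_i follows the exact
Poisson-binomial distribution (a plain binomial when all p_i are equal).
"""

from __future__ import annotations

import numpy as np
from pyteomics import mass as pmass

__all__ = [
    "D_MASS_SHIFT",
    "PROTON_MASS",
    "peptide_composition",
    "natural_isotope_peaks",
    "poisson_binomial",
    "binomial_weights",
    "convolve_peak_lists",
    "merge_peaks",
    "to_mz",
]

D_MASS_SHIFT = 1.006277  # Da per H->D substitution
PROTON_MASS = 1.00727646688


def peptide_composition(sequence: str) -> pmass.Composition:
    """Elemental composition of the intact (neutral) peptide, termini included."""
    return pmass.Composition(sequence=sequence)


def _element_distribution(element: str) -> tuple[np.ndarray, np.ndarray]:
    """(masses, abundances) of one atom's isotopes, indexed by extra neutrons."""
    iso = pmass.nist_mass[element]
    entries = sorted((num, m, ab) for num, (m, ab) in iso.items() if num != 0 and ab > 0)
    base = entries[0][0]
    size = entries[-1][0] - base + 1
    masses = np.zeros(size)
    probs = np.zeros(size)
    for num, m, ab in entries:
        masses[num - base] = m
        probs[num - base] = ab
    return masses, probs


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray], threshold: float):
    """Convolve two (mass, prob) aggregated distributions."""
    ma, pa = a
    mb, pb = b
    n = ma.size + mb.size - 1
    probs = np.zeros(n)
    wmass = np.zeros(n)
    for i in range(ma.size):
        if pa[i] == 0:
            continue
        contrib = pa[i] * pb
        probs[i : i + mb.size] += contrib
        wmass[i : i + mb.size] += contrib * (ma[i] + mb)
    keep = probs > threshold * probs.max()
    last = np.nonzero(keep)[0].max() + 1
    probs, wmass = probs[:last], wmass[:last]
    masses = np.where(probs > 0, wmass / np.where(probs > 0, probs, 1.0), 0.0)
    return masses, probs


def _power(dist, n: int, threshold: float):
    """Raise a single-atom distribution to the n-atom power."""
    result = (np.zeros(1), np.ones(1))
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base, threshold)
        n >>= 1
        if n:
            base = _convolve(base, base, threshold)
    return result


def natural_isotope_peaks(sequence: str, threshold: float = 1e-4):
    """Aggregated isotope pattern of the neutral peptide.

    Returns (masses Da, relative intensities summing to 1), truncated at
    ``threshold`` relative abundance.
    """
    comp = peptide_composition(sequence)
    acc = (np.zeros(1), np.ones(1))
    for element, count in comp.items():
        acc = _convolve(acc, _power(_element_distribution(element), count, threshold / 10), threshold / 10)
    masses, probs = acc
    keep = probs >= threshold * probs.max()
    masses, probs = masses[keep], probs[keep]
    return masses, probs / probs.sum()


def poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact distribution of the number of successes of independent Bernoullis."""
    dist = np.array([1.0])
    for p in np.asarray(probs, dtype=float):
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def binomial_weights(n: int, p: float) -> np.ndarray:
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol: float = 0.01):
    """Merge peaks closer than ``tol`` m/z (intensity-weighted positions)."""
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    out_mz: list[float] = []
    out_int: list[float] = []
    for m, i in zip(mz, intensity):
        if out_mz and m - out_mz[-1] < tol:
            tot = out_int[-1] + i
            out_mz[-1] = (out_mz[-1] * out_int[-1] + m * i) / tot
            out_int[-1] = tot
        else:
            out_mz.append(float(m))
            out_int.append(float(i))
    return np.array(out_mz), np.array(out_int)


def convolve_peak_lists(
    mz_a: np.ndarray,
    int_a: np.ndarray,
    shift: np.ndarray,
    weights: np.ndarray,
    tol: float = 0.01,
    threshold: float = 1e-6,
):
    """Cross-convolve a peak list with a discrete shift distribution.

    Every peak (m, i) spawns peaks at m + shift_k with intensity i * w_k;
    near-coincident products are merged.  Used both to deuterate a natural
    envelope and to build mixture-model components from a 0% reference.
    """
    mz = (mz_a[:, None] + shift[None, :]).ravel()
    inten = (int_a[:, None] * weights[None, :]).ravel()
    keep = inten > threshold * inten.max()
    mz, inten = merge_peaks(mz[keep], inten[keep], tol)
    return mz, inten


def to_mz(neutral_mass: np.ndarray, charge: int) -> np.ndarray:
    return (np.asarray(neutral_mass, dtype=float) + charge * PROTON_MASS) / charge
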