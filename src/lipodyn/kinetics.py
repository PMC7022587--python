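"""Protection-factor kinetics: biphasic fits, pooling, residue-level maps.

Within one population a peptide's amides rarely share a rate: the uptake curve
is fitted with one or two stretched-exponential phases (fast and slow site
groups).  Dividing the random-coil average rate of the same sites by the
observed rate gives the protection factor Pf = k_rc / k_obs, binned into the
conventional color classes (red Pf < 10, orange 10 <= Pf < 100, green
100 <= Pf < 1000, blue Pf >= 1000; prolines black, undetermined grey).

Bimodal peptides are split between two chain pools — the major population to
the "dimer" pool, the minor to the "monomer" pool (abundance ratio ~1 means
the populations cannot be told apart and both go to the dimer pool, flagged);
unimodal peptides join both pools.  Within each pool, per-residue protection
factors are resolved from the overlapping peptides: each peptide carries a
multiset of phase Pf values (one per exchangeable site), randomly assigned to
its residues and then permuted by greedy swap descent (exhaustive enumeration
on small instances) until aligned residues agree across peptides.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import aic, fit_single_stretched, fit_two_phase
from .peptides import PeptideRecord, exchangeable_positions

__all__ = [
    "Phase",
    "PhaseFit",
    "PeptidePf",
    "PooledPeptide",
    "ResiduePf",
    "PoolPfMap",
    "ABUNDANCE_CUTOFF",
    "fit_biphasic",
    "protection_factor",
    "classify_pf",
    "round_site_counts",
    "pool_peptides",
    "assign_residue_pf",
    "build_pf_chart",
]

#: minor/major abundance ratios at or above this are treated as "~1"
ABUNDANCE_CUTOFF = 0.75

PF_CLASS_EDGES = (10.0, 100.0, 1000.0)
PF_CLASSES = ("red", "orange", "green", "blue")


@dataclass(frozen=True)
class Phase:
    n_sites: float
    rate: float  # 1/s
    beta: float


@dataclass(frozen=True)
class PhaseFit:
    phases: tuple[Phase, ...]  # fast first
    rss: float
    n_exch: int

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def fit_biphasic(
    times: np.ndarray,
    di: np.ndarray,
    n_exch: int,
    seed: int = 0,
    fix_total: bool = True,
    beta_bounds: tuple[float, float] = (0.3, 1.0),
) -> PhaseFit:
    """Fit DI(t) with one or two stretched-exponential phases.

    The one-phase model uses all n_exch sites; the two-phase model splits them
    (N_fast + N_slow = n_exch when ``fix_total``).  The phase count is chosen
    by corrected-AIC comparison; two phases need at least 6 time points.
    """
    times = np.asarray(times, dtype=float)
    di = np.asarray(di, dtype=float)
    if times.size < 4:
        raise ValueError("at least 4 time points are required")
    k1, b1, rss1 = fit_single_stretched(times, di, n_exch, beta_bounds=beta_bounds)
    one = PhaseFit((Phase(float(n_exch), k1, b1),), rss1, n_exch)
    if times.size < 6:
        return one
    two_raw = fit_two_phase(
        times, di, n_exch, seed=seed, fix_total=fix_total, beta_bounds=beta_bounds
    )
    floor = times.size * (1e-8 * max(float(np.max(di)), 1.0)) ** 2
    p2 = 5 if fix_total else 6
    # a phase carrying less than half a site is not identifiable
    degenerate = min(two_raw.n_fast, two_raw.n_slow) < 0.5
    if not degenerate and aic(two_raw.rss, times.size, p2, floor) < aic(rss1, times.size, 2, floor):
        fast = Phase(two_raw.n_fast, two_raw.k_fast, two_raw.beta_fast)
        slow = Phase(two_raw.n_slow, two_raw.k_slow, two_raw.beta_slow)
        if fast.rate < slow.rate:
            fast, slow = slow, fast
        return PhaseFit((fast, slow), two_raw.rss, n_exch)
    return one


def protection_factor(k_obs: float, k_rc_avg: float) -> float:
    """Pf = k_rc / k_obs: >1 means exchange slowed by structure."""
    if k_rc_avg <= 0:
        raise ValueError("random-coil rate must be positive")
    if k_obs < 0:
        raise ValueError("observed rate must be non-negative")
    if k_obs == 0:
        return float("inf")
    return k_rc_avg / k_obs


def classify_pf(pf: float, is_proline: bool = False, undetermined: bool = False) -> str:
    """Color class of a protection factor (half-open bins as conventionally drawn)."""
    if is_proline:
        return "black"
    if undetermined or not pf >= 0 or (isinstance(pf, float) and math.isnan(pf)):
        return "grey"
    if math.isinf(pf):
        return "blue"
    idx = int(np.searchsorted(PF_CLASS_EDGES, pf, side="right"))
    return PF_CLASSES[idx]


def round_site_counts(counts: list[float], total: int) -> list[int]:
    """Largest-remainder rounding of fitted site counts to integers summing to total."""
    counts = [max(c, 0.0) for c in counts]
    s = sum(counts)
    scaled = [c * total / s if s > 0 else total / len(counts) for c in counts]
    floors = [int(math.floor(c)) for c in scaled]
    remainder = total - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: scaled[i] - floors[i], reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    return floors


@dataclass(frozen=True)
class PeptidePf:
    """Per-population fit summary of one peptide, ready for pooling."""

    peptide: PeptideRecord
    is_bimodal: bool
    relative_abundance: float  # minor/major, in (0, 1]
    populations: dict  # label ('slow'|'fast'|'all') -> PhaseFit
    pf: dict  # label -> tuple of per-phase Pf (fast first, matching PhaseFit)
    major_is_slow: bool = True


@dataclass(frozen=True)
class PooledPeptide:
    """A peptide inside one chain pool, with its per-residue Pf multiset."""

    peptide: PeptideRecord
    pf_multiset: tuple[float, ...]  # one Pf per exchangeable site
    population: str
    ambiguous: bool = False

    @property
    def positions(self) -> list[int]:
        return [self.peptide.start + p - 1 for p in exchangeable_positions(self.peptide)]


def _pool_entry(item: PeptidePf, label: str, ambiguous: bool = False) -> PooledPeptide:
    fitres = item.populations[label]
    pfs = item.pf[label]
    n_int = round_site_counts([ph.n_sites for ph in fitres.phases], fitres.n_exch)
    multiset: list[float] = []
    for pf_val, n in zip(pfs, n_int):
        multiset.extend([pf_val] * n)
    return PooledPeptide(item.peptide, tuple(multiset), label, ambiguous)


def pool_peptides(
    items: list[PeptidePf], cutoff: float = ABUNDANCE_CUTOFF
) -> tuple[list[PooledPeptide], list[PooledPeptide]]:
    """Split peptides into (dimer, monomer) pools by bimodal abundance.

    Bimodal with minor/major ratio below ``cutoff``: the major (slow)
    population represents two co-migrating chains -> dimer pool; the minor
    (fast) one -> monomer pool.  Ratio at or above the cutoff: the two
    populations are equally abundant, both are kept in the dimer pool and
    flagged ambiguous.  Unimodal peptides join both pools.
    """
    dimer: list[PooledPeptide] = []
    monomer: list[PooledPeptide] = []
    for item in items:
        if not item.is_bimodal:
            entry = _pool_entry(item, "all")
            dimer.append(entry)
            monomer.append(entry)
        elif item.relative_abundance < cutoff:
            major = "slow" if item.major_is_slow else "fast"
            minor = "fast" if item.major_is_slow else "slow"
            dimer.append(_pool_entry(item, major))
            monomer.append(_pool_entry(item, minor))
        else:
            dimer.append(_pool_entry(item, "slow", ambiguous=True))
            dimer.append(_pool_entry(item, "fast", ambiguous=True))
    return dimer, monomer


@dataclass(frozen=True)
class ResiduePf:
    position: int  # 1-based on the parent sequence
    residue: str
    pf: float  # NaN when undetermined
    color: str
    status: str  # resolved | conflict | undetermined | proline


@dataclass(frozen=True)
class PoolPfMap:
    sequence: str
    entries: tuple[ResiduePf, ...]
    cost: float
    converged: bool
    conflicts: tuple[int, ...]  # residue positions with unresolved disagreement
    assignments: tuple[tuple[float, ...], ...] = ()  # final per-peptide value order

    def colors(self) -> list[str]:
        return [e.color for e in self.entries]


def _assignment_cost(vals: list[np.ndarray], coverage: dict[int, list[tuple[int, int]]]) -> float:
    cost = 0.0
    for slots in coverage.values():
        if len(slots) < 2:
            continue
        logs = np.log10([vals[p][s] for p, s in slots])
        cost += float(np.var(logs))
    return cost


def _residue_contrib(
    vals: list[np.ndarray], coverage: dict[int, list[tuple[int, int]]], residue: int
) -> float:
    slots = coverage.get(residue, [])
    if len(slots) < 2:
        return 0.0
    logs = np.log10([vals[p][s] for p, s in slots])
    return float(np.var(logs))


def _class_consistent(vals, coverage) -> bool:
    for slots in coverage.values():
        classes = {classify_pf(vals[p][s]) for p, s in slots}
        if len(classes) > 1:
            return False
    return True


def _multiset_perm_count(values: tuple[float, ...]) -> int:
    n = math.factorial(len(values))
    for _, group in itertools.groupby(sorted(values)):
        n //= math.factorial(len(list(group)))
    return n


def _distinct_permutations(values: tuple[float, ...]):
    """Distinct permutations of a multiset, without enumerating duplicates."""
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    items = sorted(counts)
    n = len(values)

    def rec(prefix: list[float]):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in items:
            if counts[v]:
                counts[v] -= 1
                prefix.append(v)
                yield from rec(prefix)
                prefix.pop()
                counts[v] += 1

    yield from rec([])


def assign_residue_pf(
    pool: list[PooledPeptide],
    sequence: str,
    seed: int = 17,
    n_restarts: int = 20,
    patience: int = 200,
    exhaustive_limit: int = 100_000,
    class_level: bool = True,
) -> PoolPfMap:
    """Resolve per-residue protection factors from overlapping peptides.

    Each peptide holds a fixed multiset of Pf values (its phase Pf values,
    each repeated by the integer site count).  Values are assigned to the
    peptide's exchangeable residues at random (seeded) and improved by
    within-peptide swaps that lower the inconsistency cost — the summed
    variance of log10 Pf across the peptides covering each residue — until
    the cost reaches zero (or, with ``class_level``, until all aligned
    residues share a color class) or a patience window passes without
    improvement; up to ``n_restarts`` random restarts keep the best state.
    When the joint permutation space is at most ``exhaustive_limit`` states
    the optimum is found by exhaustive enumeration instead.  The per-peptide
    multisets are conserved by construction at every step.

    Residues whose covering peptides still disagree are reported as conflicts
    (never silently averaged into a "resolved" status); prolines are black and
    positions never covered by an exchangeable site are grey/undetermined.
    """
    rng = np.random.default_rng(seed)
    positions = [pep.positions for pep in pool]
    for pep, pos in zip(pool, positions):
        if len(pos) != len(pep.pf_multiset):
            raise ValueError(
                f"peptide {pep.peptide.peptide_id}: {len(pep.pf_multiset)} Pf values "
                f"for {len(pos)} exchangeable residues"
            )
    coverage: dict[int, list[tuple[int, int]]] = {}
    for p_idx, pos in enumerate(positions):
        for s_idx, res in enumerate(pos):
            coverage.setdefault(res, []).append((p_idx, s_idx))

    def finish(vals: list[np.ndarray]) -> PoolPfMap:
        cost = _assignment_cost(vals, coverage)
        conflicts = []
        per_res: dict[int, float] = {}
        for res, slots in sorted(coverage.items()):
            arr = np.array([vals[p][s] for p, s in slots])
            agree = (
                len({classify_pf(v) for v in arr}) == 1
                if class_level
                else float(np.ptp(np.log10(arr))) < 1e-9
            )
            per_res[res] = 10.0 ** float(np.mean(np.log10(arr)))
            if not agree:
                conflicts.append(res)
        if conflicts:
            warnings.warn(
                f"no fully consistent assignment found; {len(conflicts)} residue(s) "
                f"in conflict: {conflicts[:10]}",
                stacklevel=2,
            )
        entries = []
        for i, aa in enumerate(sequence, start=1):
            if aa == "P":
                entries.append(ResiduePf(i, aa, float("nan"), "black", "proline"))
            elif i in conflicts:
                entries.append(ResiduePf(i, aa, per_res[i], "grey", "conflict"))
            elif i in per_res:
                entries.append(ResiduePf(i, aa, per_res[i], classify_pf(per_res[i]), "resolved"))
            else:
                entries.append(ResiduePf(i, aa, float("nan"), "grey", "undetermined"))
        converged = not conflicts
        return PoolPfMap(
            sequence,
            tuple(entries),
            cost,
            converged,
            tuple(conflicts),
            tuple(tuple(float(v) for v in arr) for arr in vals),
        )

    def is_done(vals) -> bool:
        if class_level:
            return _class_consistent(vals, coverage)
        return _assignment_cost(vals, coverage) < 1e-12

    # exhaustive route on small instances
    space = 1
    for pep in pool:
        space *= _multiset_perm_count(pep.pf_multiset)
        if space > exhaustive_limit:
            break
    if space <= exhaustive_limit:
        best_vals, best_cost = None, np.inf
        perm_lists = [list(_distinct_permutations(pep.pf_multiset)) for pep in pool]
        for combo in itertools.product(*perm_lists):
            vals = [np.array(c) for c in combo]
            cost = _assignment_cost(vals, coverage)
            if cost < best_cost:
                best_vals, best_cost = vals, cost
                if cost == 0.0:
                    break
        return finish(best_vals)

    best_vals, best_cost = None, np.inf
    swappable = [i for i, pep in enumerate(pool) if len(set(pep.pf_multiset)) > 1]
    for _ in range(n_restarts):
        vals = []
        for pep in pool:
            arr = np.array(pep.pf_multiset, dtype=float)
            rng.shuffle(arr)
            vals.append(arr)
        cost = _assignment_cost(vals, coverage)
        stale = 0
        while cost > 1e-12 and stale < patience and swappable:
            p = int(rng.choice(swappable))
            n_slots = len(vals[p])
            i, j = rng.choice(n_slots, size=2, replace=False)
            if vals[p][i] == vals[p][j]:
                stale += 1
                continue
            ri, rj = positions[p][i], positions[p][j]
            before = _residue_contrib(vals, coverage, ri) + _residue_contrib(vals, coverage, rj)
            vals[p][i], vals[p][j] = vals[p][j], vals[p][i]
            after = _residue_contrib(vals, coverage, ri) + _residue_contrib(vals, coverage, rj)
            if after < before - 1e-15:
                cost += after - before
                stale = 0
            else:
                vals[p][i], vals[p][j] = vals[p][j], vals[p][i]
                stale += 1
        cost = _assignment_cost(vals, coverage)  # re-sum to kill drift
        if cost < best_cost:
            best_vals, best_cost = [v.copy() for v in vals], cost
        if is_done(best_vals):
            break
    return finish(best_vals)


def build_pf_chart(dimer_map: PoolPfMap, monomer_map: PoolPfMap):
    """Per-residue chart rows for the three chains (dimer x2, monomer x1).

    The dimer-pool assignment is duplicated for the two dimer chains; the
    monomer pool fills the hairpin chain.  Returns a pandas DataFrame with
    one row per residue and a color column per chain.
    """
    import pandas as pd

    if dimer_map.sequence != monomer_map.sequence:
        raise ValueError("pool maps must share the parent sequence")
    rows = []
    for d_entry, m_entry in zip(dimer_map.entries, monomer_map.entries):
        rows.append(
            {
                "residue_index": d_entry.position,
                "residue": d_entry.residue,
                "dimer_chain_1": d_entry.color,
                "dimer_chain_2": d_entry.color,
                "monomer_chain": m_entry.color,
                "pf_dimer": d_entry.pf,
                "pf_monomer": m_entry.pf,
            }
        )
    return pd.DataFrame(rows)
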