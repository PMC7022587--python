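"""Biphasic fits, protection factors, pooling, residue-level assignment."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipodyn.kinetics import (
    PeptidePf,
    Phase,
    PhaseFit,
    PooledPeptide,
    assign_residue_pf,
    build_pf_chart,
    classify_pf,
    fit_biphasic,
    pool_peptides,
    protection_factor,
    round_site_counts,
)
from lipodyn.peptides import PeptideRecord, exchangeable_positions


class TestClassify:
    @pytest.mark.parametrize(
        "pf,expected",
        [(5, "red"), (50, "orange"), (500, "green"), (5000, "blue"),
         (10, "orange"), (100, "green"), (1000, "blue"), (9.999, "red"),
         (float("inf"), "blue")],
    )
    def test_half_open_bins(self, pf, expected):
        assert classify_pf(pf) == expected

    def test_proline_black_and_undetermined_grey(self):
        assert classify_pf(50.0, is_proline=True) == "black"
        assert classify_pf(float("nan")) == "grey"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pf=st.floats(0.0, 1e6))
    def test_boundaries_are_half_open(self, pf):
        """classify(10-eps) is red, classify(10) orange, and so on."""
        color = classify_pf(pf)
        lo = {"red": 0.0, "orange": 10.0, "green": 100.0, "blue": 1000.0}[color]
        hi = {"red": 10.0, "orange": 100.0, "green": 1000.0, "blue": np.inf}[color]
        assert lo <= pf < hi


class TestProtectionFactor:
    def test_equal_rates_give_unity(self):
        assert protection_factor(1e-3, 1e-3) == pytest.approx(1.0)

    def test_thousandfold_slowdown(self):
        assert protection_factor(1e-5, 1e-2) == pytest.approx(1000.0)

    def test_zero_observed_rate_is_infinitely_protected(self):
        assert math.isinf(protection_factor(0.0, 1e-2))
        assert classify_pf(protection_factor(0.0, 1e-2)) == "blue"


class TestRoundSiteCounts:
    def test_largest_remainder(self):
        assert round_site_counts([3.6, 4.4], 8) == [4, 4]
        assert round_site_counts([3.7, 4.1], 8) == [4, 4]
        assert round_site_counts([1.2, 1.2, 5.6], 8) == [1, 1, 6]

    def test_sum_constraint(self):
        for counts in ([2.3, 5.2], [0.1, 0.1, 7.5], [8.0]):
            assert sum(round_site_counts(counts, 8)) == 8


class TestFitBiphasic:
    def test_single_rate_curve_selects_one_phase(self):
        t = np.logspace(0, 4, 12)
        di = 8 * (1 - np.exp(-0.01 * t))
        fit = fit_biphasic(t, di, 8)
        assert fit.n_phases == 1
        assert fit.phases[0].rate == pytest.approx(0.01, rel=0.01)
        assert fit.phases[0].beta == pytest.approx(1.0, abs=1e-3)

    def test_two_rate_groups_recovered_within_five_percent(self):
        """(N, k) = (4, 1e-1) and (4, 1e-4), noise-free adaptive grid."""
        t = np.logspace(-1.5, 5.5, 30)
        di = 4 * (1 - np.exp(-0.1 * t)) + 4 * (1 - np.exp(-1e-4 * t))
        fit = fit_biphasic(t, di, 8, seed=0)
        assert fit.n_phases == 2
        fast, slow = fit.phases
        assert fast.rate == pytest.approx(0.1, rel=0.05)
        assert slow.rate == pytest.approx(1e-4, rel=0.05)
        assert fast.n_sites + slow.n_sites == pytest.approx(8.0, abs=0.5)
        # independent coarse grid-search oracle around the generation values
        best = min(
            (
                (float(np.sum((4 * (1 - np.exp(-kf * t)) + 4 * (1 - np.exp(-ks * t)) - di) ** 2)), kf, ks)
                for kf in np.logspace(-2, 0, 21)
                for ks in np.logspace(-5, -3, 21)
            )
        )
        assert math.isclose(best[1], fast.rate, rel_tol=0.15)
        assert math.isclose(best[2], slow.rate, rel_tol=0.15)

    def test_experimental_six_point_grid_is_fittable(self):
        times = np.array([30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0])
        di = 8 * (1 - np.exp(-((3e-4 * times) ** 0.8)))
        fit = fit_biphasic(times, di, 8)
        assert fit.phases[0].rate == pytest.approx(3e-4, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 time points"):
            fit_biphasic(np.array([1.0, 10.0, 100.0]), np.zeros(3), 5)


def _item(pep, is_bimodal, ratio, pf_by_label, n_exch, major_is_slow=True):
    pops, pfs = {}, {}
    for label, pf_vals in pf_by_label.items():
        n_per = n_exch / len(pf_vals)
        phases = tuple(Phase(n_per, 1e-3 / pf, 1.0) for pf in pf_vals)
        pops[label] = PhaseFit(phases, 0.0, n_exch)
        pfs[label] = tuple(pf_vals)
    return PeptidePf(pep, is_bimodal, ratio, pops, pfs, major_is_slow)


class TestPoolPeptides:
    def setup_method(self):
        self.pep = PeptideRecord("AKLAVDEG", 1, 8)
        self.n = len(exchangeable_positions(self.pep))

    def test_bimodal_half_ratio_splits_major_to_dimer(self):
        item = _item(self.pep, True, 0.5, {"slow": (200.0,), "fast": (2.0,)}, self.n)
        dimer, monomer = pool_peptides([item])
        assert [p.population for p in dimer] == ["slow"]
        assert [p.population for p in monomer] == ["fast"]

    def test_unimodal_goes_to_both_pools(self):
        item = _item(self.pep, False, 1.0, {"all": (50.0,)}, self.n)
        dimer, monomer = pool_peptides([item])
        assert len(dimer) == len(monomer) == 1
        assert dimer[0] is monomer[0]

    def test_near_unity_ratio_flagged_ambiguous_in_dimer_pool(self):
        item = _item(self.pep, True, 0.9, {"slow": (200.0,), "fast": (2.0,)}, self.n)
        dimer, monomer = pool_peptides([item], cutoff=0.75)
        assert len(dimer) == 2 and all(p.ambiguous for p in dimer)
        assert monomer == []

    def test_multiset_lengths_match_site_counts(self):
        item = _item(self.pep, True, 0.5, {"slow": (200.0, 5.0), "fast": (2.0,)}, self.n)
        dimer, monomer = pool_peptides([item])
        assert len(dimer[0].pf_multiset) == self.n
        assert len(monomer[0].pf_multiset) == self.n


def _pool_from_truth(seq, spans, truth):
    pool = []
    for start, end in spans:
        pep = PeptideRecord(seq[start - 1 : end], start, end)
        pos = [pep.start + p - 1 for p in exchangeable_positions(pep)]
        pool.append(PooledPeptide(pep, tuple(truth[i] for i in pos), "all"))
    return pool


class TestAssignResiduePf:
    seq = "AKLAVDEGFRLMSEKA"

    def test_single_peptide_single_phase_uniform(self):
        pep = PeptideRecord(self.seq[:8], 1, 8)
        n = len(exchangeable_positions(pep))
        pool = [PooledPeptide(pep, (50.0,) * n, "all")]
        m = assign_residue_pf(pool, self.seq, seed=1)
        resolved = [e for e in m.entries if e.status == "resolved"]
        assert all(e.pf == pytest.approx(50.0) for e in resolved)
        assert len(resolved) == n

    def test_two_overlapping_peptides_recover_generated_classes(self):
        """Exact recovery, cross-checked against exhaustive enumeration."""
        truth = {i: (5.0 if i <= 6 else 500.0) for i in range(3, 13)}
        spans = [(1, 8), (5, 12)]
        pool = _pool_from_truth(self.seq, spans, truth)
        # greedy path (exhaustive route disabled) must match the brute force
        m = assign_residue_pf(pool, self.seq, seed=4, exhaustive_limit=0)
        assert m.converged and m.cost == pytest.approx(0.0, abs=1e-12)
        # brute-force oracle: enumerate all within-peptide permutations
        positions = [p.positions for p in pool]
        best = np.inf
        for perms in itertools.product(
            *(set(itertools.permutations(p.pf_multiset)) for p in pool)
        ):
            cov = {}
            for pi, (pos, vals) in enumerate(zip(positions, perms)):
                for r, v in zip(pos, vals):
                    cov.setdefault(r, []).append(v)
            cost = sum(np.var(np.log10(v)) for v in cov.values() if len(v) > 1)
            best = min(best, cost)
        assert best == pytest.approx(0.0, abs=1e-12)
        for e in m.entries:
            if e.status == "resolved":
                assert classify_pf(e.pf) == classify_pf(truth[e.position])

    def test_non_overlapping_peptides_converge_immediately(self):
        truth = {i: float(10 ** (i % 4)) for i in range(1, 17)}
        pool = _pool_from_truth(self.seq, [(1, 7), (9, 16)], truth)
        m = assign_residue_pf(pool, self.seq, seed=0)
        assert m.cost == 0.0 and m.converged

    def test_multiset_conserved_by_assignment(self):
        truth = {i: (5.0 if i % 3 else 800.0) for i in range(1, 17)}
        pool = _pool_from_truth(self.seq, [(1, 10), (4, 13), (7, 16)], truth)
        m = assign_residue_pf(pool, self.seq, seed=9, exhaustive_limit=0, n_restarts=3)
        for pep, final in zip(pool, m.assignments):
            assert sorted(final) == sorted(pep.pf_multiset)

    def test_contradictory_peptides_reported_not_silent(self):
        # same span, irreconcilable multisets -> conflict warning
        pep = PeptideRecord(self.seq[:8], 1, 8)
        n = len(exchangeable_positions(pep))
        pool = [
            PooledPeptide(pep, (5.0,) * n, "all"),
            PooledPeptide(pep, (5000.0,) * n, "all"),
        ]
        with pytest.warns(UserWarning, match="conflict"):
            m = assign_residue_pf(pool, self.seq, seed=0)
        assert not m.converged and len(m.conflicts) == n
        assert all(e.color == "grey" for e in m.entries if e.status == "conflict")

    def test_seeded_reproducibility(self):
        truth = {i: (5.0 if i % 2 else 300.0) for i in range(1, 17)}
        pool = _pool_from_truth(self.seq, [(1, 9), (5, 13), (8, 16)], truth)
        a = assign_residue_pf(pool, self.seq, seed=7, exhaustive_limit=0)
        b = assign_residue_pf(pool, self.seq, seed=7, exhaustive_limit=0)
        assert a.assignments == b.assignments


class TestBuildChart:
    def test_three_chain_rows(self):
        seq = "AKLPAVDE"
        pepD = PeptideRecord(seq[:8], 1, 8)
        n = len(exchangeable_positions(pepD))
        dimer = assign_residue_pf([PooledPeptide(pepD, (500.0,) * n, "all")], seq, seed=0)
        pepM = PeptideRecord(seq[4:8], 5, 8)
        nm = len(exchangeable_positions(pepM))
        monomer = assign_residue_pf([PooledPeptide(pepM, (5.0,) * nm, "all")], seq, seed=0)
        chart = build_pf_chart(dimer, monomer)
        assert list(chart["dimer_chain_1"]) == list(chart["dimer_chain_2"])
        # proline black in all three rows
        row_p = chart[chart["residue"] == "P"].iloc[0]
        assert row_p["dimer_chain_1"] == row_p["monomer_chain"] == "black"
        # residue covered only by the dimer pool is grey in the monomer row
        row3 = chart[chart["residue_index"] == 3].iloc[0]
        assert row3["dimer_chain_1"] == "green" and row3["monomer_chain"] == "grey"
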