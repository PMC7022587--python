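# Methods

This note documents the models, parameter choices and numerical decisions
behind `lipodyn`, and what the synthetic-data validation does and does not
establish about real data.

## Elastic-scan analysis

The elastic intensity of a predominantly incoherent scatterer is modeled in
the Gaussian approximation, `I_el(Q) = I0 exp(−⟨u²⟩Q²/6)`, and the MSD is the
(−6×) slope of a weighted linear fit of ln I on Q². Weights are 1/σ² with
σ_lnI = σ_I/I; when every σ is zero (noise-free synthetic scans) the fit is
unweighted and exact. Whether experimental MSD fits should be weighted is not
settled practice, so both modes exist (weights follow the data; zero σ ⇒
unweighted).

The approximation degrades beyond ⟨u²⟩Q² ≈ 2. The package flags points beyond
that limit and reports the valid fraction per temperature but keeps the fixed
instrument window by default (warn-only policy): ambient-temperature scans of
soft particles violate the limit at the high-Q edge, and dropping points per
temperature would make the MSD series inconsistent across temperatures.
Callers wanting a strict policy can apply the returned mask.

Force constants use `⟨k⟩ = 0.00276 / (d⟨u²⟩/dT)` per temperature segment. The
quotient (not product) orientation is deliberate: resilience is the inverse
of how fast thermal displacement grows, so the softest regime (largest MSD
slope) must get the smallest constant. Segments are split at breakpoints
{200, 250} K by default — the conventional dynamical-transition and
lipid-related inflection temperatures — and a point exactly at a breakpoint
belongs to both adjacent segments (the piecewise model is continuous there;
with noise-free data this is exact, with noisy data it is a negligible,
symmetric shared anchor). Breakpoints are user-configurable; no automatic
change-point detection is attempted, since the choice is acknowledged to be
partly conventional. A segment fitted with non-positive slope is flagged
`rigid/undefined` rather than given a negative constant.

Ramp protocols are emulated by sampling every 0.3 K (one sample per minute at
0.3 K/min) and binned to 5 K intervals anchored at the lowest temperature,
averaging intensities per Q point (uncertainties in quadrature/n) and
reporting bin centers. Averaging intensities over a 5 K bin of an exponential
in T introduces a relative bias of order (Q²Δ⟨u²⟩/6)²/12 ≈ 10⁻⁵ — far below
the fit tolerances.

Absorption is handled as a scalar transmission in `normalize_scan`
(subtract empty cell, divide by transmission, divide by vanadium); full
geometry-dependent absorption coefficients and multiple-scattering
corrections are out of scope.

## Random-coil exchange rates

Per-residue intrinsic rates follow the standard random-coil calibration:
acid-, base- and water-catalyzed channels with multiplicative side-chain
factors of the residue itself and its left neighbor, free-terminus
corrections, and per-channel Arrhenius scaling from the 20 °C reference.
The constants live in `src/lipodyn/data/rc_rate_constants.yaml` (version 1,
"hd-2020"), transcribed from the poly-DL-alanine H→D literature; the file
records its provenance and is swappable via `load_rate_constants(path)`,
because published revisions of these constants differ slightly and no single
revision is canonical. Titratable groups (Asp, Glu, His, C-terminal
carboxyl) mix their protonated/deprotonated factors through the
Henderson–Hasselbalch ratio at the working pD; His (pKa 7.42 in D₂O) is the
one that matters near pD 7.2 — a His neighbor legitimately breaks the
otherwise ×10-per-pD-unit base-channel scaling. The D₂O ion product uses a
van't Hoff temperature correction (ΔH = 14.2 kcal/mol about pK 15.05 at
20 °C); side-chain pKa values are treated as temperature-independent, a
sub-percent effect over the 0–20 °C range used here.

Every protection factor in the package is a *ratio* of rates computed from
the same table, so Pf results are invariant to the absolute calibration.

The per-peptide "random-coil average rate" is defined operationally, as in
the kinetic analysis itself: fit `DI(t) = N(1 − exp(−(kt)^β))` on a 30-point
log-spaced grid between the curve's 1% and 99% average-completion times. The
completion times are solved in log-time (Brent, relative tolerance), and the
fit runs in dimensionless time t/t₁, which makes the fitted rate exactly
equivariant under a uniform rescaling of all rates — the property that lets
a uniform protection factor be recovered as a clean ratio of fitted rates.
Experimental fits use the measured time points instead.

Site bookkeeping: residue 1 of a peptide has no measured amide and residue 2
back-exchanges faster than any practical quench, so the first two residues
(configurable `n_term_excluded`) and all prolines are excluded from
exchangeable-site counts, rate profiles and uptake sums.

## Envelopes and deconvolution

Isotopic fine structure is computed from residue elemental compositions
(pyteomics' standard table) by multinomial expansion per element with
exponentiation-by-squaring, tracking the intensity-weighted mean mass of each
aggregated peak and truncating at 10⁻⁴ relative abundance. Deuteration adds
1.006277 Da per D; the D count across sites with per-site probabilities p_i
is the exact Poisson-binomial distribution in the generator. Products closer
than 0.01 m/z are merged intensity-weighted, which preserves centroids
exactly and matches unit-resolution ion-trap data.

Deconvolution fits each envelope as a one- or two-component mixture in which
a component is the peptide's measured 0% envelope convolved with a binomial
deuteration distribution binomial(N_exch, DI/N_exch) — tying the model to
the real isotope pattern rather than a free Gaussian. Parameters (component
uptakes and one weight) come from a 31-point coarse uptake grid with the
weight solved in closed form per pair, refined by bounded least squares with
tight tolerances. One- versus two-component choice uses a BIC-style score
with the residual floored at (10⁻⁷)² per point (so noise-free unimodal data
do not produce 0/0 comparisons); two components must win by ΔBIC > 10, a
deliberately conservative threshold that avoids spurious bimodality, and a
fit whose components sit within 0.25 D or whose minor weight vanishes is
reported as unimodal. The generator's populations are Poisson-binomial while
the deconvolution component is binomial; this small model mismatch is the
dominant weight error on kinetically generated envelopes (≈0.01–0.015 at
2:1 mixtures) and vanishes when populations are generated at uniform
per-site probability.

DI from centroids uses the two-point control mapping
`DI = (m_t − m_0)/(m_80 − m_0) × 0.8 × N_exch`; the charge cancels in the
ratio. The apparent back-exchange percentage of a run is reported from the
same controls. Slightly negative DI at early times is clamped to 0 (warning
beyond 0.1 D). If the 80% control is missing the analysis falls back to the
uncorrected mass shift with a warning.

The population abundance ratio is read at the first experimental time point,
where centroid separation is largest; if that point is unimodal the earliest
bimodal point is used and flagged.

## Kinetic fits and protection factors

Uptake curves are fitted with one or two stretched-exponential phases
(multistart bounded least squares in dimensionless time, seeded). With the
site-count sum fixed to N_exch the two-phase model has 5 parameters; model
choice uses corrected AIC where defined (plain AIC on 6-point grids, where
the correction term is singular), and a two-phase fit carrying less than half
a site in either phase collapses to one phase. β is bounded to [0.3, 1] for
experimental grids to avoid degenerate stretching on 6 points; the
random-coil reference fit allows (0, 1]. Sites that do not exchange within
the 10⁴-s window produce phases whose rate — and hence Pf magnitude — is not
identifiable, only bounded below; such phases are honestly reported with
their (large) fitted ratio and land in the blue (Pf ≥ 1000) class, which is
the meaningful statement.

Pf = k_rc/k_obs, oriented so protection gives Pf ≥ 1. Pooling: bimodal
peptides with minor/major abundance below 0.75 (configurable) send the major
population to the dimer pool and the minor to the monomer pool; ratios at or
above the cutoff are indistinguishable from 1:1 and keep both populations in
the dimer pool flagged ambiguous; unimodal peptides join both pools. The
cutoff value is a design choice — observed ratios cluster near 1 and near
0.5, and 0.75 is the midpoint.

Residue-level resolution: each pooled peptide carries a multiset of phase Pf
values, each repeated by its integer site count (largest-remainder rounding
constrained to sum to N_exch). The solver assigns values to residues at
random (seeded) and improves by within-peptide swaps that lower the summed
variance of log₁₀ Pf across the peptides covering each residue, evaluated
incrementally on the two residues a swap touches; 20 restarts, patience 200
rejected proposals. When the joint space of distinct per-peptide permutations
is ≤10⁵ the optimum is found exhaustively instead. Consistency is judged at
color-class level by default (exact-value agreement is an option): phase Pf
values are averages over site groups, so exact equality across peptides with
different phase structure is not generally attainable even for a correct
assignment. Multisets are conserved by construction; residues whose covering
peptides still disagree are reported as conflicts and colored grey, never
silently averaged into "resolved".

## Synthetic data: what it does and does not emulate

The generator reproduces the features the analysis depends on: stepped and
ramped temperature protocols, Gaussian-approximation intensities with
counting-like noise (σ = noise_fraction × √(I/I_max) relative to the base
peak), overlapping digests (a seeded tiling-plus-random-spans scheme — a
coverage model, not a protease-specificity model), per-residue kinetic
deuteration from k_rc/Pf, two-population mixtures at stated weights,
isotopic fine structure, 0%/80% controls, and uniform back exchange (12%
default, applied to controls as in a real workflow). It does not emulate
chromatographic peak shapes, retention-time alignment, charge-state
interference, instrument resolution functions, or EX1/EX2 mechanistic
crossover; passing tests therefore validate the estimators against their own
forward model, not those instrument effects. Envelope peak-width/resolution
is a free emulation parameter (aggregated unit-resolution peaks are used, as
appropriate for ion-trap data).

Default study conditions: pD 7.2, 273.15 K, times {30, 100, 300, 1000, 3000,
10⁴} s, labeling-buffer D fraction 1.0 (0.9/0.95 dilution scenarios are
supported), back exchange 0.12, MSD breakpoints {200, 250} K. The packaged
apoA-I fixture is the standard public 243-residue mature sequence.

## Problem sizes and determinism

Tests and examples run digests of a few to ~40 peptides and full-length
elastic protocols (25 stepped temperatures; 967 ramp samples → 58 bins);
these sizes exercise every code path while keeping the whole suite under a
minute. All stochastic stages (noise, digestion, multistart initialization,
assignment restarts) draw from seeded NumPy generators; fixed seeds give
byte-identical output files, and every seed used is recorded in the run log.

## Known limitations

- Protection factors of phases slower than the observation window are
  class-identifiable only (blue), not magnitude-identifiable.
- The deconvolution's binomial component slightly misfits strongly
  heterogeneous populations (Poisson-binomial truth); weight errors stay
  within ~0.02 noise-free.
- The random-coil constant table is one published revision among several;
  absolute rates carry that systematic, protection factors do not.
- `pool_peptides` encodes the dimer/monomer (two-pool) chain model; other
  chain stoichiometries would need a different pooling rule.
- mzML import is an extension point (convert to the peak TSV schema), not
  implemented in core.
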