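# Random-coil amide H->D exchange calibration, version 1 ("hd-2020").
#
# Poly-DL-alanine reference rates and side-chain inductive/steric factors for
# backbone amide hydrogen exchange into D2O, in the Englander-laboratory
# parameterization (Bai/Connelly/Englander random-coil calibration).
# Transcribed to the maintainers' best knowledge of that literature; the file
# is versioned and swappable, and every downstream quantity that is a rate
# ratio (protection factor) is independent of the absolute values here.
#
# Factor semantics, all log10:
#   acid_own/base_own  -- effect of a residue's side chain on its OWN amide
#   acid_next/base_next-- effect on the amide of the FOLLOWING residue
# The water channel uses the base-channel factors.
version: 1
name: hd-2020
exchange_direction: H-to-D (protein H into D2O)
reference_rates:
  # log10 rates for poly-DL-alanine at T_ref; acid/base in 1/(M*min), water in 1/min
  log_k_acid: 1.62
  log_k_base: 10.18
  log_k_water: -1.50
  T_ref_K: 293.15
activation_energies_kcal_per_mol:
  acid: 14.0
  base: 17.0
  water: 19.0
pK_D2O:
  value_at_T_ref: 15.05
  # van't Hoff enthalpy for the D2O autoionization, kcal/mol
  delta_H_kcal_per_mol: 14.2
side_chain_pKa_D2O:
  D: 4.48
  E: 4.93
  H: 7.42
  C_term: 4.00
termini:
  # free N-terminal amine: extra factors on the amide of residue 2
  N_term: {acid_next: -1.32, base_next: 1.62}
  # C-terminal carboxyl(ate): extra factors on the last residue's own amide
  C_term_deprotonated: {acid_own: 0.96, base_own: -1.80}
  C_term_protonated: {acid_own: 0.05, base_own: 0.00}
residues:
  A: {acid_own: 0.00, acid_next: 0.00, base_own: 0.00, base_next: 0.00}
  R: {acid_own: -0.59, acid_next: -0.32, base_own: 0.08, base_next: 0.22}
  N: {acid_own: -0.58, acid_next: -0.13, base_own: 0.49, base_next: 0.32}
  D:
    deprotonated: {acid_own: 0.90, acid_next: 0.58, base_own: 0.10, base_next: -0.18}
    protonated: {acid_own: -0.90, acid_next: -0.12, base_own: 0.69, base_next: 0.60}
  C: {acid_own: -0.54, acid_next: -0.46, base_own: 0.62, base_next: 0.55}
  E:
    deprotonated: {acid_own: -0.90, acid_next: 0.31, base_own: -0.11, base_next: -0.15}
    protonated: {acid_own: -0.60, acid_next: -0.27, base_own: 0.24, base_next: 0.39}
  Q: {acid_own: -0.47, acid_next: -0.27, base_own: 0.06, base_next: 0.20}
  G: {acid_own: -0.22, acid_next: 0.22, base_own: 0.27, base_next: 0.17}
  H:
    protonated: {acid_own: -0.80, acid_next: -0.51, base_own: 0.80, base_next: 0.83}
    deprotonated: {acid_own: 0.00, acid_next: 0.00, base_own: -0.10, base_next: 0.14}
  I: {acid_own: -0.91, acid_next: -0.59, base_own: -0.73, base_next: -0.23}
  L: {acid_own: -0.57, acid_next: -0.13, base_own: -0.58, base_next: -0.21}
  K: {acid_own: -0.56, acid_next: -0.29, base_own: -0.04, base_next: 0.12}
  M: {acid_own: -0.64, acid_next: -0.28, base_own: -0.01, base_next: 0.11}
  F: {acid_own: -0.52, acid_next: -0.43, base_own: -0.24, base_next: 0.06}
  P: {acid_own: null, acid_next: -0.19, base_own: null, base_next: -0.24}
  S: {acid_own: -0.44, acid_next: -0.39, base_own: 0.37, base_next: 0.30}
  T: {acid_own: -0.79, acid_next: -0.47, base_own: -0.07, base_next: 0.20}
  W: {acid_own: -0.40, acid_next: -0.44, base_own: -0.41, base_next: -0.11}
  Y: {acid_own: -0.41, acid_next: -0.37, base_own: -0.27, base_next: 0.05}
  V: {acid_own: -0.74, acid_next: -0.30, base_own: -0.70, base_next: -0.14}
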