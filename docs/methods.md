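# Methods

This note documents the models and estimators implemented in `cochap`,
the assumptions behind them, the synthetic-data conditions under which
they are validated, and the numerical choices that affect reproducibility.

## Scope and data model

The package covers three stages of the analysis of a cochaperone/Hsp70
(J-domain protein / Hsp70) interaction study:

1. **interface geometry** of two-chain complexes and conformational
   ensembles,
2. **free-energy post-processing** of biased-sampling data (umbrella
   sampling and well-tempered metadynamics on one or two collective
   variables),
3. **interface coevolution detection** between two partner protein
   families sharing one species phylogeny.

Atomistic simulation itself, docking, homology modelling and tree
inference are out of scope: structures, trajectories (as CV time series
or multi-model PDB), alignments and trees are inputs. Internal units are
nm, kJ/mol and K; `k_B = 0.0083144621 kJ/mol/K`; the default temperature
is 310 K, so `kT = 2.5775 kJ/mol`.

## Interface geometry

* **Contacts**: pairs of non-hydrogen atoms across two disjoint residue
  selections within 0.5 nm. All cutoffs in the package are strict (`<`);
  the convention matters for reproducing counts and is applied uniformly
  (contacts, ion pairs, H-bonds, state classification).
* **Ion pairs**: oppositely charged side-chain groups (Arg guanidine
  NE/CZ/NH1/NH2, Lys NZ, Asp CG/OD1/OD2, Glu CD/OE1/OE2) whose
  mass-weighted centres of mass are closer than 0.5 nm. Terminal
  amine/carboxylate groups are not considered. Groups with missing atoms
  are skipped with a warning.
* **Hydrogen bonds**: donor-acceptor distance < 0.35 nm and
  hydrogen-donor-acceptor angle < 30 deg. Donors are N/O/S atoms with a
  covalently attached hydrogen (< 0.12 nm, same residue). If a structure
  contains no hydrogens at all — common for crystal structures — the
  angle criterion is skipped and only the distance criterion applies;
  the downgrade is reported as a warning and each unordered pair is then
  reported once.
* **SASA**: Shrake-Rupley quadrature with a deterministic golden-spiral
  grid (default 960 points/atom), probe 0.14 nm, Bondi-type element
  radii (configurable table; unknown elements fall back to 0.17 nm with
  a warning). The quadrature resolution is `sum_atoms 4 pi (r+p)^2 / n_points`;
  area comparisons (including rigid-body invariance, which cannot be
  exact for any fixed-orientation grid) are made at this tolerance.
  Buried hydrophobic surface is the SASA of hydrophobic residues
  ({Ala, Val, Leu, Ile, Met, Phe, Trp, Pro}; Gly excluded; configurable)
  of each chain in isolation minus the same atoms' SASA in the complex.
* **Superposition/clustering**: Kabsch SVD superposition with a
  determinant correction (always a proper rotation); single-linkage
  clustering is the connected components of the pairwise RMSD < cutoff
  graph (default 0.18 nm), with the centroid frame minimizing summed
  within-cluster RMSD (ties to the lowest frame index, making the result
  independent of frame order).
* **Charge fractions**: positive = {Arg, Lys}, negative = {Asp, Glu};
  His is uncharged by default (flag to change), unknown residue names
  count as uncharged with a warning.

## Free-energy estimators

* **WHAM** iterates the standard self-consistent equations on a uniform
  histogram (default 100 bins over the pooled sample range), with
  restraint energies evaluated at bin centres, convergence when the
  maximum change of any window offset drops below 1e-8 kJ/mol, and
  unvisited bins reported as `+inf`, never extrapolated. The sampled
  region must be connected: if the visited bins split into two islands
  each holding >= 5% of the samples, the estimator refuses and names the
  gap (the offset across an unsampled gap would be pure extrapolation);
  smaller stray islands are tolerated. Uncertainties come from a Monte
  Carlo bootstrap that resamples each window's samples with replacement
  (samples are treated as decorrelated draws; see the simulator note
  below).
* **Well-tempered metadynamics** reconstruction uses
  `F(s) = -(gamma/(gamma-1)) V_bias(s)`, re-zeroed at the minimum.
  Surfaces from bias snapshots are averaged after aligning each map to
  its own finite minimum (the gauge is arbitrary; per-bin SD is reported
  alongside). Populations can be obtained from the averaged map or
  averaged over per-block populations; both orders are one line each
  with `integrate_state_populations` / `average_fes_blocks` and differ
  only through the gauge-alignment nonlinearity.
* **Probabilities and state populations**: `p ~ exp(-F/kT)` per bin on
  the uniform grid; the four ion-pair interaction states (bound/bound,
  bound only on coordinate 1, only on 2, neither) are quadrants of the
  2D surface with bins assigned by their centres, strict `<` at the
  0.5 nm threshold.
* **Reweighting**: biased frames are returned to the unbiased ensemble
  with `exp((U_i(r) - F_i)/kT)` using the WHAM offsets `F_i`; per-bin
  weighted means of any observable follow. Empty bins are reported as
  missing, never as zero.

## Evolutionary models

**Independent model.** Each column evolves under the N-state symmetric
equal-frequency chain normalized to one expected substitution per unit
time, with a per-column rate multiplier; transition probabilities are
closed form, and the likelihood is computed by Felsenstein pruning with
gaps as missing data and a uniform root distribution. The state space is
restricted to the residues observed in the column (flag for the full 20);
an invariant column has likelihood 1 on its restricted space and an
unidentifiable rate, reported as 0.

**Coevolution model.** Two columns form a single Markov chain on the
product space `S = A1 x A2`. Only single-position changes are allowed; a
change landing in the *profile* `P` (the favoured residue combinations)
has rate `s`, all other changes rate `d`. The stationary distribution is
`pi(x) ~ (s/d)^[x in P]` and the chain is reversible, which gives the
likelihood engine its speed: the symmetrized generator is diagonalized
once per `s/d` ratio (`Q(s,d) = d Q(s/d,1)`, so eigenvectors depend on
the ratio only) and each branch costs two matrix-vector products in the
eigenbasis. Pairs with a gap in either column are missing data.

**Fitting and dAIC.** Both models have k = 2 free parameters (two column
rates; `s` and `d` with the profile fixed to the residue pairs observed
co-occurring in the data), so `dAIC = AIC_independent - AIC_coev =
2 (logL_coev - logL_independent)`. The coevolution fit is an outer
bounded 1-D search over `log(s/d)` (five dispersed grid points plus the
ratio-1 point, then a bracketed refinement) with an exact inner 1-D
search over `log d`; the ratio-1 start makes the fit no worse than a
matched independent model, so the null dAIC distribution sits slightly
above zero rather than straddling it. Parameter bounds are
[1e-5, 1e3] on both rates; non-convergence is flagged on the result, not
silent.

**Significance calibration.** The dAIC threshold is the 99th percentile
(linear-interpolation definition) of dAIC values obtained by refitting
column pairs simulated under the independent model on the same tree — a
parametric bootstrap that absorbs both the phylogenetic correlation and
the systematic positive offset of the statistic. Calls use `>=`
(ties included). Pairs with fewer than 4 ungapped shared species are
skipped, not fitted. An important empirical property, documented because
it drives the study design below: the null dAIC distribution widens
rapidly with per-column residue diversity (the observed-pairs profile
lets the model concentrate probability on the observed support, and the
size of that support relative to the product space sets the scale), so a
valid null must match the data's column diversity.

**Parameter recovery caveat.** With the profile fixed to observed pairs,
the fitted `s/d` is a structurally inflated measure of support
concentration (it is far above 1 even on independent data) and should
not be read as the generative rate ratio. Recovery of the generative
ratio is well behaved when the fit is given the generative profile
(`CoevPairModel(profile=...)`), and that is how the recovery checks are
run; the scan and calibration always use the observed-pairs profile.

**Ancestral reconstruction** is marginal empirical Bayes: per-node
posteriors proportional to below-subtree times above-tree partial
likelihoods under the independent model.

**Profile-HMM column filter.** A profile HMM is built from the alignment
itself (match states = columns with < 50% gaps; transition and emission
counts from the aligned sequences' own paths with +1 pseudocounts), and
forward-backward gives each residue the posterior probability of its
assigned state (match, or flanking insert for residues in non-match
columns). Residues with posterior below 0.7 are replaced by gaps;
masking is per residue, not per column — the alignment layout is kept.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their arguments and a master seed
(independent named substreams via `SeedSequence`, reproducible across
platforms).

* **Trees**: Yule (pure-birth) trees, ultrametric, strictly positive
  branches. Default birth rate 4.0 at 64 taxa gives ~0.9 expected
  substitutions/site root-to-tip and total length ~16 — the divergence
  scale of a typical single-protein ortholog family; a unit birth rate
  would give a saturated tree (~4 substitutions/site root-to-tip).
* **Alignments**: the independent simulator uses the exact closed-form
  transition probabilities; the coevolution simulator is the generative
  counterpart of the fitted model, run by exact Gillespie simulation
  along each branch from a stationary root draw, optionally on a
  restricted per-column alphabet. Neither emulates indels, rate
  heterogeneity across sites beyond the supplied per-column rates,
  alignment error, or non-reversible/profile-mixture substitution
  processes of real proteins — passing tests show estimator correctness
  and calibration logic, not robustness to real-alignment pathologies.
* **Toy complexes**: two pseudo-peptide chains separated by a 1.2 nm
  gap, with three planted bridging features whose geometry is exact by
  construction (an Arg-Asp ion pair at a 0.45 nm group-COM distance, a
  Ser-OG hydrogen bond at 0.30 nm / 10 deg, and a Leu-Leu hydrophobic
  stack), plus seeded sub-0.02 nm jitter on the generic residues. The
  margins make accidental features geometrically impossible, so the
  ground-truth lists are exhaustive. These are detector fixtures, not
  physical structures.
* **Biased sampling**: overdamped Euler-Maruyama Langevin dynamics on
  analytic 1D/2D potentials (`dt = 2e-5`, friction 1, kT at 310 K). The
  step size keeps the discretization inflation of the stationary
  variance of the stiffest restraint (2500 kJ/mol/nm^2) below ~3%.
  Umbrella walkers start at their window centres with 2000 unrecorded
  equilibration steps. Metadynamics follows the well-tempered protocol
  (default hills 0.1 kJ/mol x 0.04 nm, deposition every 250 steps, bias
  factor 15, one walker — multiple walkers only parallelize sampling and
  do not change the estimator) with the bias and its analytic gradient
  accumulated on a 0.01 nm grid, bilinear interpolation for the force,
  and reflective walls at the grid edges. Samples are autocorrelated
  over ~20 steps (restraint relaxation), which the WHAM bootstrap
  ignores; its SEs are therefore mildly optimistic on these data.

## Validation study conditions

The acceptance-style benchmarks (`cochap.benchmarks`, driven by
`tests/test_acceptance.py` and `scripts/acceptance.py`) run at these
fixed problem sizes, chosen once so the whole suite completes in minutes
on a single CPU:

* **WHAM**: harmonic potential (kappa 200 kJ/mol/nm^2), 5 windows at
  -0.2..0.2 nm with spring 2500 kJ/mol/nm^2, 1e5 samples/window, 100
  bins. The recovered profile is compared with the analytic potential
  over the windows' design coverage (restrained means +- 3 sigma of the
  restrained Gaussian) after removing the arbitrary additive constant by
  mean alignment; measured RMS error is ~0.04-0.05 kT against a 0.2 kT
  requirement.
* **Metadynamics**: separable double well with barrier 7.5 kJ/mol
  (~2.9 kT) along x and a 500 kJ/mol/nm^2 harmonic channel in y;
  1.5e6 steps, hills every 250 steps. The barrier is read off the
  x-projection of the block-averaged surface (last 8 of 15 bias
  snapshots); measured error ~0.05-0.2 kT against a 0.5 kT requirement.
* **Coevolution**: 64-leaf Yule tree (birth rate 4, seed fixed).
  Null/independent columns evolve at rate 0.25, reproducing the ~5
  residues/column diversity of real ortholog families at this depth —
  at that diversity the null 99th-percentile dAIC threshold is ~15-19,
  the same order as thresholds calibrated on real interface alignments.
  The threshold is calibrated on 2500 independent null pairs and tested
  on 2000 fresh pairs (type-I error 1% by construction; the sizes keep
  combined quantile-plus-binomial noise inside a 3-SE band). The planted
  coevolving pair lives on the 6-letter charged/amide alphabet
  {D,E,K,R,N,Q} with the six charge/polarity-compensating profile pairs
  (D-K, E-R, K-D, R-E, N-Q, Q-N) — the fast-switching compensated
  interface position this analysis targets — at per-position rate ~2
  (d = 0.25 for s/d = 10, d = 0.286 for s/d = 5). Power is measured on
  25 replicates of a 3x3 interface scan (planted pair plus two
  independent columns per side); generative-profile fits on the same
  replicates measure ratio recovery.

## Known limitations

* The dAIC statistic is calibration-dependent: thresholds transfer only
  between data of comparable column diversity and tree depth. The
  pooled-null design follows the all-pairs pooling convention; per-pair
  thresholds are not implemented.
* The two-parameter coevolution model ignores amino-acid exchangeability
  structure (all single-position moves are s or d); it is a detector of
  joint preference, not a mechanistic substitution model.
* WHAM assumes decorrelated samples within windows (a block-bootstrap
  flag is the obvious extension and is not implemented); metadynamics
  assumes the bias has entered the well-tempered quasi-stationary regime
  before the averaged snapshots begin.
* The SASA quadrature is exact only for isolated spheres; all area
  statements carry the stated grid resolution.
* The profile-HMM filter scores residues against a profile built from
  the same alignment; with very few sequences the +1 pseudocounts
  dominate and posteriors are uninformative.
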