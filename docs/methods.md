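# Methods

`lidex` quantifies a sparsely populated ("excited") protein conformation
that exchanges with the major ("ground") conformation on the
micro-to-millisecond timescale, and relates that exchange to structural
ensembles and trajectories of the two states.  This note documents the
models, the numerical choices, and what the synthetic data do and do not
emulate.

## Two-state exchange model for CPMG dispersion

The system is a two-site exchange A ⇌ B with forward rate k₁, reverse
rate k₋₁, exchange rate k_ex = k₁ + k₋₁ and populations
p_A = k₋₁/k_ex, p_B = k₁/k_ex (p_B ≤ 0.5 by convention).  During a
constant-time CPMG element of length T_relax containing an even number
n of ideal, instantaneous refocusing pulses (ν_cpmg = n / 2T_relax), the
transverse coherence evolves under the Bloch–McConnell equations.  For a
single coherence with offset ω of state B relative to state A, the
evolution generator between pulses is the 2×2 complex matrix

    L(ω) = [ −k₁        k₋₁        ]
           [  k₁   −k₋₁ − iω      ]

and a refocusing pulse inverts the sign of the accumulating offset.  The
magnetization starts at the equilibrium populations (the constant-time
element is preceded by a recovery delay much longer than 1/k_ex), is
propagated through the train τ–π–(2τ–π)ⁿ⁻¹–τ with τ = T_relax/2n, and
the reported rate is

    R2,eff = R2,0 − (1/T_relax) · ln( |M_A(T_relax)| / p_A ),

the magnitude of the ground-state component relative to a reference
experiment without the relaxation element.  Propagation is exact for
ideal pulses (closed-form 2×2 matrix exponentials, binary-exponentiation
matrix powers), so no Carver–Richards-style approximation enters.
Off-resonance and finite-pulse effects are not modelled.

Two experiment types share this engine:

* **¹⁵N single-quantum**: a single pathway with ω = Δω_N converted from
  ppm at the heteronucleus frequency (γ_N/γ_H = 0.10136 in magnitude;
  only |Δω| enters).
* **¹³C–¹H multiple-quantum (methyl TROSY)**: the ¹³C pulses interconvert
  the double- and zero-quantum pathways, which evolve with offsets
  Δω_C ± Δω_H (γ_C/γ_H = 0.25144).  Both pathways are propagated and
  their signals averaged before the logarithm.  With Δω_H = 0 the MQ
  model collapses exactly to the single-pathway case.

**Equal intrinsic relaxation.** The exchange-free rate R2,0 is assumed
equal in both states; it then commutes with the evolution and enters
R2,eff as an additive per-probe, per-field baseline.  This is what makes
the fitting fast (below) and is the standard assumption when the minor
state is a few percent populated.

**MQ branch ambiguity.** Because the DQ/ZQ average depends only on the
unordered offset pair {ω_C + ω_H, |ω_C − ω_H|}, the parameter pairs
(Δω_C, Δω_H) and their rad/s-equivalent swap produce identical curves.
Fits are reported on the branch with the larger carbon term
(ω_C ≥ ω_H); the relative sign of Δω_H versus Δω_C cancels exactly in
the pathway average and is exposed only for per-pathway diagnostics.

## Fitting protocol

1. **Error floor**: σ(R2,eff) is raised to 2% of R2,eff when smaller.
2. **Inclusion filter**: curves with an exchange contribution
   Rex = R2,eff(ν_min) − R2,eff(ν_max) below 2 s⁻¹ (maximum over
   fields) are excluded and reported.
3. **Grid search**: χ² is minimized at each node of a (k_ex, p_B) grid
   (default: k_ex log-spaced 100–10000 s⁻¹ × p_B 0.005–0.20) with all
   per-probe parameters free.  Because baselines are linear they are
   profiled out in closed form; the remaining per-probe shift
   differences (one or two parameters) are fitted by bounded
   trust-region least squares from both a warm start (previous node)
   and an analytic fast-exchange initial guess.  Failed nodes become
   missing cells.  Two identifiability diagnostics are attached: a flat
   surface (no exchange information) and a fast-exchange ridge (nodes
   within Δχ² = 9.21 of the minimum spanning a more than 3-fold k_ex
   range), the latter signalling that populations may not be reliably
   extractable.
4. **Global fit**: (k_ex, p_B) shared over all curves are refined by a
   Nelder–Mead simplex on the profile χ² (log k_ex and
   logit p parametrization), per-probe parameters re-optimized at every
   evaluation.  Because the simplex starts at the best grid node, the
   final χ² never exceeds that node's.
5. **Monte-Carlo errors**: 40 parametric repeats (R2,eff resampled from
   N(value, σ)) refit globally; the per-parameter standard deviation over
   repeats is the reported precision.  Deterministic given a seed; more
   than 25% failed repeats raises a flag.
6. **Jackknife**: each probe is left out in turn and the data refit; a
   probe whose removal moves k_ex by more than 3 Monte-Carlo standard
   deviations is flagged as reporting a different exchange process (the
   3-σ criterion is this package's choice; the protocol itself only
   prescribes the purpose).

The profile strategy (2 shared parameters outer, ≤2 nonlinear + linear
baselines per probe inner) reaches the same optimum as a joint fit of
all ~90 parameters but is far more robust and an order of magnitude
faster.

## Thermo-kinetics

With κ = 1 and T in kelvin (integer kelvin as reported, not +0.15):

    k₁ = k_ex·p_B,  k₋₁ = k_ex·p_A,  t½ = ln2/k
    ΔG  = −RT ln(p_B/p_A)
    ΔG‡ = −RT ln(k·h / (k_B·T))

CODATA constants; energies carried in J/mol, reported in kJ/mol.  The
identity ΔG = ΔG‡(forward) − ΔG‡(reverse) holds algebraically and is
enforced by tests.  Note that recomputing derived quantities from
*rounded* fit values shifts the last printed digit: p = 3.2% and
k_ex = 2490 s⁻¹ give t½(ground) = 8.70 ms and ΔG‡ = 61.05 kJ/mol, which
published tables based on unrounded fits may show as 8.6 ms and
61.0 kJ/mol.

## Distance restraints and pseudo-atoms

NOESY cross-peaks are converted to bounds by intensity class: 2–4 Å
(strong, short mixing), 4–6 Å (weak, short mixing), 4–8 Å (seen only at
long mixing), 2–6 Å for amide–amide peaks, 2–8 Å when only one mixing
time exists; hydrogen-bond restraints restrain donor H within 2 Å and
donor N within 3 Å of the acceptor (the geometric pairing of the
published 2/3 Å limits — the N is one covalent bond further from the
acceptor; the source text is ambiguous about the order).  Methyl–methyl
distances are measured between the barycenters (unweighted centroids)
of the three methyl protons; r⁻⁶ averaging is available as a
sensitivity option but is not the primary definition.  Satisfaction is
judged against upper bounds with a configurable tolerance
(default 0.5 Å, typical NOE slack); lower bounds are reported but do
not determine violation by default.

Against an ensemble, satisfaction is evaluated on the representative
(medoid) conformer by default — how a bundle "satisfies" a restraint is
not otherwise standardized — with a fraction-of-members rule as an
option.  Two-state partitioning classifies every restraint as
A-only / B-only / both / neither; counts always sum to the total.

## Ensemble geometry

Superposition is closed-form Kabsch (SVD with a determinant guard, so
reflections are never applied); fewer than 3 atoms or collinear
selections are rejected.  Region RMSD fits one selection and measures
another; the default selections mirror the analysis this package
implements: fit on the rigid scaffold (residues 40–97 + 137–220 for
trajectory clustering, 11–97 + 137–223 for two-state ensemble
comparison), measure on the mobile segment 98–136.  All user-facing
residue numbers are author numbering from the input files.

Pairwise region-RMSD matrices feed Ward hierarchical clustering
(scipy linkage on the condensed matrix).  When the cluster number is not
given, k ∈ [2, 10] maximizing the mean silhouette (precomputed-distance
metric) is chosen, ties toward smaller k; an all-zero matrix yields one
cluster.  Cluster centroids are medoids (member minimizing summed RMSD
to co-members) and the spread is the mean member-to-medoid RMSD.  RMSF
superposes every model on the ensemble mean over a fit selection (one
mean re-iteration) and reports per-residue root-mean-square deviations.

## Trajectory violation statistic

For N state-specific methyl pairs {ij} with thresholds
d_ij^viol = ⟨d_ij⟩ + 2σ(d_ij) taken over the 20-member reference bundle
(population σ — the bundle is the complete reference set, not a
sample), the per-frame statistic is

    V(t) = (1/N) Σ_ij max(0, d_ij(t) − d_ij^viol).

Classification against the home state (the trajectory's starting
conformation) and the other state uses moving-average smoothing
(window 10 frames) and thresholds ε_stable = 0.5 Å, ε_arrive = 0.5 Å,
ε_depart = 1.0 Å over the final 20% of frames: "stable" when the home
violation never exceeds ε_stable, "transitioned" when the trajectory
ends compatible with the other state and away from its own, otherwise
"neither".  The three behaviours are only described qualitatively in
the literature this implements; the numeric defaults are this package's
choice, configurable and documented here.

## Synthetic data

The generators provide every input with known ground truth:

* **Dispersion**: forward-model R2,eff with multiplicative Gaussian
  noise of 2% of the rate, matching the error-floor convention (noise on
  the rate rather than on peak intensities; the intensity/rate
  conversion itself is round-trip tested separately).  The
  wild-type-like preset
  is 21 MQ probes, 700 + 850 MHz, 16 ν values 66–2000 Hz (T = 30 ms),
  p_B = 3.2%, k_ex = 2490 s⁻¹, 293 K, with per-probe |Δω_C| drawn
  0.3–2.2 ppm, |Δω_H| 0.02–0.25 ppm, baselines 8–20 s⁻¹ — ranges
  typical of methyl probes under chemical exchange.
* **Toy two-state system**: a rigid helical core (30 residues, ILE
  methyls with real atom naming every third residue) plus an 8-residue
  mobile segment; conformation B displaces the mobile segment rigidly
  by a stated amount (default 20 Å, the scale of the open/closed
  separation), partly sideways and partly back along the core so both
  conformations form methyl contacts with the core.  A reproducible
  0.05 Å coordinate ruffle avoids perfectly regular geometry.
* **Reference bundles**: n noisy copies of one conformation
  (default 20 models, 0.3 Å per-coordinate noise — bundle spreads
  comparable to a refined NMR ensemble).
* **Jump trajectories**: a telegraph process between the conformations
  (per-frame switch probability, or one forced switch), linear
  interpolation over 4 frames at switches, plus coordinate noise.

Every generator is a pure function of its parameters and a seed.  What
the synthetic data do **not** emulate: force-field physics, correlated
coordinate fluctuations, spectral artefacts (peak overlap, t₁ noise),
scalar/dipolar relaxation differences between exchange states, or
partial transitions.  Tests passing on these data therefore validate
the statistical machinery and geometry, not the ability to cope with
real-data pathologies such as overlapping peaks or non-two-state
dynamics.

## Problem sizes and determinism

The test suite and the acceptance script run the full recovery
experiment at the study's conditions (21 probes × 2 fields × 16
frequencies, 10 independent seeds) with a 6 × 5 initialization grid —
a deliberate choice: the grid only seeds the continuous global fit, so
a coarse grid changes runtime, not the optimum.  Library defaults keep
the published 25 × 20 grid.  All stochastic operations take explicit
seeds and are reproducible bit-for-bit; Monte-Carlo uses 40 repeats by
default per the protocol, with smaller counts in unit tests.

## Known limitations

* Exchange models are strictly two-state; linear three-state topologies
  are out of scope.
* Ideal-pulse propagation ignores off-resonance tilt and finite pulse
  width (relevant above ~2 kHz ν_cpmg at low pulse power).
* Temperature-series (van't Hoff) analysis is not provided; each
  temperature is fitted separately.
* Cross-protein ensemble comparison requires a user-supplied residue
  correspondence; no sequence alignment is performed.
* Restraint evaluation assumes author residue numbering is consistent
  between states; heteroatom naming beyond PDB v3 conventions is not
  normalized.
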