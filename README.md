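# lidex

Quantitative analysis of a transiently populated protein conformation:
two-state CPMG relaxation-dispersion fitting, thermo-kinetic
interpretation, NOE distance-restraint partitioning between structural
states, conformational-ensemble geometry, and trajectory
restraint-violation monitoring — with a synthetic-data module so every
stage runs, and is tested, without any downloads.

The package is written for NMR spectroscopists and simulators studying
micro-to-millisecond conformational exchange — the situation where a
domain samples a minor ("excited") conformation at a few percent
population, invisible to crystallography but detectable by CPMG
relaxation dispersion and state-specific NOEs.  The motivating system is
a chaperone N-terminal domain whose nucleotide-binding lid exchanges
between an open ground state and a transiently closed excited state.

## The model

Two-site exchange A ⇌ B with rate k_ex = k₁ + k₋₁ and minor population
p_B.  Effective transverse relaxation during a constant-time CPMG train
is computed by exact propagation of the 2×2 complex Bloch–McConnell
blocks through the echo train (ideal pulses), for ¹⁵N single-quantum and
¹³C–¹H multiple-quantum (methyl-TROSY) coherences; the MQ dispersion
depends on both |Δω_C| and |Δω_H| through the DQ/ZQ pathway average.
Fitting follows the standard protocol: 2% error floor on σ(R2,eff),
exclusion of curves with Rex < 2 s⁻¹, a (k_ex, p_B) grid search with all
per-probe parameters profiled, a global fit sharing (k_ex, p_B) across
curves, 40 Monte-Carlo repeats for precision, and leave-one-probe-out
jackknife for consistency.  Fitted parameters feed the thermo-kinetic
chain

    k₁ = k_ex·p_B,   ΔG = −RT ln(p_B/p_A),   ΔG‡ = −RT ln(k·h/(k_B·T))

(Eyring, κ = 1).  On the structural side: NOESY intensity classes map to
distance bounds (2–4, 4–6, 4–8, 2–6, 2–8 Å), methyl–methyl distances are
measured between proton-triplet barycenters, restraints are partitioned
by which state satisfies them, ensembles are compared by Kabsch
superposition / region RMSD / Ward clustering with automatic cluster
number, and trajectories are scored with the per-frame violation
statistic V(t) = (1/N) Σ max(0, d_ij − ⟨d_ij⟩ − 2σ(d_ij)).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

The thermo-kinetic chain from a dispersion fit
(`python examples/thermo_chain.py`):

```
k1 (ground->excited)  =    79.68 s^-1
k-1 (excited->ground) =  2410.32 s^-1
half-life ground      =     8.70 ms
half-life excited     =    0.288 ms
dG (excited - ground) =     8.31 kJ/mol
dG++ ground -> TS     =    61.05 kJ/mol
dG++ excited -> TS    =    52.75 kJ/mol
```

The ground state lives ~9 ms and the excited state ~0.3 ms; the 8.3
kJ/mol gap corresponds to a ~3% minor population at 293 K, and the
Eyring barriers (κ = 1) set the millisecond interconversion timescale.

A full synthetic fitting run (`python examples/fit_dispersion.py`,
a few minutes) generates a 21-probe two-field MQ dataset with 2% noise
at (p_B = 3.2%, k_ex = 2490 s⁻¹), then recovers those parameters by
grid search + global fit with Monte-Carlo errors.  Other examples cover
restraint partitioning, ensemble clustering/RMSF, trajectory violation
monitoring, and (with user-fetched PDB files) comparisons against
deposited ensembles — one script per capability under `examples/`.

A thin CLI wraps the same library calls:

```bash
lidex simulate cpmg --seed 1 --out disp.csv
lidex fit-cpmg disp.csv --outdir fit/
lidex thermo --kex 2490 --p-excited 0.032 --temp 293
```

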