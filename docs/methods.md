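# Methods

This note records the models implemented in `rbslib`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Translation-initiation thermodynamics (`rbslib.biophysics`)

The translation initiation rate of a protein-coding sequence is scored by a
five-term Gibbs free-energy balance between two states of the mRNA: the
free, folded initial state and the final state in which the 30S ribosomal
subunit is bound, the last nine nucleotides of the 16S rRNA (the
anti-Shine-Dalgarno tail, organism-specific: `ACCUCCUUA` for the
gram-negative hosts in the registry, `ACCUCCUUU` for *B. subtilis* and
*C. glutamicum*) are hybridized to the mRNA, and all structures that would
clash with the hybridization site or the ribosome footprint are unfolded:

    ΔG_total = ΔG_mRNA:rRNA + ΔG_start + ΔG_spacing + ΔG_standby − ΔG_mRNA
    r = rate_scale · exp(−β · ΔG_total)

with β = 0.45 mol/kcal and rate_scale = 2,500 au, so that common
physiological rates land between ~1 and 100,000 au on a proportional (not
absolute) scale. The RBS is by convention the 35 nucleotides before the
start codon; `MRNAContext` renormalizes the leader/RBS boundary
accordingly.

Candidate 16S pairing sites are enumerated as 9-nt windows whose 3′ edge
lies 0–20 nt upstream of the start codon. For each window the engine
returns the duplex energy and where pairing actually ends inside the
window; the *aligned spacing* is measured from that 3′-most paired base to
the start codon. Each candidate's final-state energy combines the duplex
with the refolding of the mRNA upstream of the window and downstream of the
ribosome footprint (footprint default: 13 nt of CDS; the mRNA considered
for folding extends 35 nt into the CDS). The minimum-total candidate wins;
ties break toward the spacing closest to the optimum, then the
most-upstream site. Bases between the window start and the first paired
base are conservatively left unfolded.

Parameters not fixed by prior measurement are configuration with defaults:

* **Spacing penalty** (0 at the 5-nt optimum, ≥ 0 elsewhere): compressed
  branch `0.5·d²` kcal/mol (d = spacing − 5 < 0); stretched branch
  saturates as `6·d²/(d²+16)` kcal/mol. Both branches are monotone away
  from the optimum; the exact measured curve is not public, so only these
  qualitative constraints are load-bearing.
* **Start-codon energies** (kcal/mol): AUG = GUG = −1.19 (most negative),
  UUG = −0.54, CUG = −0.34; other codons are rejected as start codons.
* **Standby-site term**: constant 0 by default, kept as an explicit hook.

Two folding engines satisfy one contract (`mfe_fold`, `hybridize`):
`ViennaEngine` adapts the ViennaRNA nearest-neighbor model (Turner
parameters; results are memoized, and tiny positive minimum-free-energy
artefacts are clamped to 0 since the open chain is always admissible), and
`ToyEngine` is a deterministic stand-in for engine-independent work — fold
energies from an explicit table (default 0) and ungapped antiparallel
duplex scoring at GC −3, AU −2, GU −1 kcal/mol. Algorithmic tests run on
the toy engine; the Vienna adapter has its own behavioral tests.

## Degenerate-library design (`rbslib.degenerate`, `rbslib.design`)

A degenerate RBS is a string over the 16-letter IUPAC alphabet; its library
size is the product of per-position cardinalities, and the design space for
a 35-nt RBS has 16³⁵ members. Expansion is lexicographic and refuses above
10⁶ variants (callers switch to uniform seeded sampling); internally all
sequences are RNA (`T` → `U`).

Coverage discretizes log10 rate space between r_min and r_max into
`B_total = ceil(log10(r_max/r_min)/W)` bins (W = search resolution; 17 bins
for a 1–100,000 au range at W = 0.30). Bin centers sit at
`r_min·10^(W(k+½))`; a bin at y is filled when some variant's predicted
rate lies in `[y/10^W, y·10^W]`, boundaries inclusive — windows of adjacent
bins deliberately overlap, so one rate can fill two bins. The objective
`F = C − 0.02·N` (weight a named constant) has maximum `1 − 0.02·B_total`,
reached exactly when each bin is filled and every variant is needed.

The genetic algorithm holds a population (default 100) of degenerate
sequences, initialized non-degenerate at random (Search/Zoom) or as copies
of the wild type (Genome Editing). Each generation draws operators at 40%
recombination (random junction splice of two parents), 15% degeneracy
increase (uniform over eligible positions, then uniform over strict
superset codes), 15% degeneracy decrease (strict subsets), 15%
non-degenerate substitution, 10% unmodified elites, 5% fresh random, with
fitness-proportional parent selection on `F − min(F) + ε`. The incumbent
best is always carried over, so the best objective is non-decreasing; a
top-5 archive across all generations supplies the returned solutions.
Termination: objective maximum reached, stagnation (default 50
generations), or the iteration cap (default 500). Zoom mode is purely a
re-parameterization (narrower range, smaller W) — the test suite asserts
it shares the Search code path. Genome-Editing mode enforces, as a hard
constraint with offspring redrawing, that all differences from the wild
type fit one contiguous window (default ≤ 12 nt). Candidate libraries
larger than the expansion cap (default 10⁴) are scored on a seeded
subsample and flagged. Multi-dimensional coverage takes the Cartesian
product of per-gene bin grids; a cell counts when one clone fills every
coordinate simultaneously, and `monte_carlo_coverage` estimates the
coverage reached by sampling a finite number of random clones.

## Canonical crtEBI kinetic model (`rbslib.kinetics`)

The pathway from the isoprenoid precursors IPP/DMAPP to neurosporene is a
fixed elementary-reaction network, shipped as a versioned human-readable
reaction list (`data/crtebi_network_v1.tsv`): 24 reversible mass-action
reactions (48 rate constants) implementing 10 overall conversions — Idi
(1), IspA (2), CrtE (2), CrtB (2), CrtI (3) — each decomposed into
reversible substrate binding, reversible bound-state catalysis where
applicable, and reversible product release. Chain enzymes hand
intermediates through bound states (e.g. IspA:GPP either releases GPP or
condenses with IPP toward FPP); prephytoene exists only CrtB-bound
(processive condensation of two GGPPs). This decomposition reproduces the
aggregate counts that define the canonical model (24/48/10/5) and yields 29
species — 9 free metabolites, 5 free enzymes, 15 complexes. A printed
count of 24 species cannot be reconciled with those aggregates under any
standard chain decomposition we could construct; the network file
documents its own species count. Cofactors are not modeled.

The model is de-dimensionalized: all concentrations are ratios to a
reference pathway variant, so rate constants are apparent dimensionless
quantities and a variant enters only through its total-enzyme ratios
`e_gene = transcription multiplier × r_gene/r_gene,ref` (reference rates
72,268 / 20,496 / 203,462 au for crtE/crtB/crtI; Idi and IspA fixed at 1).
IPP and DMAPP are boundary species held at `precursor_supply` (default 1),
which makes upstream precursor engineering (a dxs sweep) a single knob; a
finite-pool mode is deliberately not the default. Initial conditions: free
enzymes at their ratios, boundary pools at supply, everything else 0.
Integration uses LSODA (rtol 1e-8, atol 1e-10 by default; the fit loop
uses 1e-6/1e-9) over the 7-h batch horizon matching the experimental
post-induction period, with a numba-compiled right-hand side when numba is
importable. The production flux is the endpoint free neurosporene divided
by 7 h, and productivities follow the calibration

    productivity = 196 µg/gDCW/h × r_p / r_p,ref ,

so the reference variant predicts its own productivity exactly, for any
valid parameter set. Enzyme totals are conserved to ≤ 1e-6 relative along
trajectories, and halving solver tolerances changes r_p by < 0.1%.

Reference-choice invariance is implemented for uniform rescaling of all
reference concentrations by λ with the compensating transform
`k′ = k·λ^(order−1)` per reaction side: trajectories scale as 1/λ and every
productivity prediction is unchanged (≤ 1e-6, tested). Per-species
rescaling does not preserve the one-constant-per-reaction mass-action form
and is intentionally not offered.

Two batch-model caveats, measured by the test suite and worth knowing:

* *Endpoint vs flux.* With all reverse constants at 0, the quasi-steady
  production flux is non-decreasing in every enzyme ratio, but the 7-h
  endpoint product can dip by a few percent when an upstream enzyme is
  raised, because the standing stock of enzyme-bound intermediates grows;
  the deviation vanishes as the horizon grows. The monotonicity test
  therefore reads the instantaneous release flux at a long horizon.
* *Precursor turnover.* Productivity rises with precursor supply while
  sub-saturating, then turns over: excess boundary IPP drives IspA:GPP
  directly toward FPP, outcompeting free-GPP release and starving CrtE's
  GPP-binding entry. This is a steady-state property of the canonical
  decomposition, present in every reversibility regime, not a solver
  artefact.

## Parameter reduction and identification (`rbslib.identify`)

Reduction removes 15 of the 48 degrees of freedom: one detailed-balance
relation per overall conversion fixes the reverse constant of that
conversion's (last) bound-state catalytic step given a configured overall
equilibrium constant (default 50, forward-favorable; 10 dependent
constants), and the five substrate-binding forward constants — one per
enzyme — are pinned (default 40, fast binding), leaving 33 free
parameters. The map is a versioned configuration object; changing it must
preserve the 33-count. `reduce`/`inverse_reduce` round-trip exactly, and
reconstruction satisfies the balance relations to machine precision.
Full sets whose pinned entries deviate are projected with a warning.

Identification minimizes the mean relative error
`mean(|pred − meas|/meas)` over the non-reference variants (the reference
anchors the scale, so the metric is invariant to rescaling all
productivities). The optimizer is a memetic GA in log10 parameter space,
bounds ±4 decades: random initial population around the default parameter
profile (σ = 0.8 decades), tournament selection, blend crossover, Gaussian
mutation, elitism; each run's best individual is polished by a bounded
trust-region least-squares step (the polish budget counts trust-region
iterations — each also pays a 33-column finite-difference Jacobian).
Simulation failures score a fixed penalty rather than aborting. Runs
(default 10) restart independently from seeds drawn off the caller's
generator; the report carries per-run errors and the cross-run dispersion
of the best-fit log-parameters as a uniqueness diagnostic.

## Synthetic data generator (`generate_synthetic_dataset`)

Characterized variant tables are not bundled, so identification and its
tests run on synthetic campaigns that emulate the study conditions: 73
design points scattered log-uniformly over the Search-mode ranges (crtE
445–72,000 au; crtB 3–20,000 au; crtI 97–203,000 au), the row closest (log
distance) to the canonical reference rates flagged as the reference,
productivities simulated from a known parameter set, renormalized so the
reference reads exactly 196 µg/gDCW/h, and multiplicative lognormal noise
(mean-1, CV = `noise_cv`) applied to non-reference rows. The default
noise CV of 0.10 reflects a typical spectrophotometric productivity
measurement; recovery tests use CV = 0 so that residual error is
attributable to the optimizer alone. The "ground-truth" parameter set for
such studies comes from a seeded helper (`example_true_parameters`):
default profile jittered log-uniformly by ±0.6 decades on the free
coordinates. What passing recovery tests show is that the pipeline
(ratios → simulation → calibration → fit) is self-consistent and
informative against a permuted-data null; they cannot certify accuracy on
wet-lab data, where model misspecification (growth effects, media,
regulation) dominates.

Desk-scale study sizes: recovery runs 2 GA restarts × (population 16 ×
6 generations) + 6 polish iterations against all 72 non-reference rows,
then scores a held-out 10-point log-uniform grid; the landscape study uses
10⁴ mutation samples per mutation count. These sizes are the package's
defaults for its own reproducibility checks.

## SEAMAP applications (`rbslib.applications`)

`SEAMAP` couples the network, an identified parameter set, and the
reference state into a productivity predictor (simulation results are
memoized per enzyme-ratio tuple; every output table carries a SHA-256
digest of the parameter set for traceability). On top of it:

* **FCCs** by central finite differences of ln(productivity) in
  ln(enzyme ratio), default relative step 1%, validated by step-halving.
  A pathway variant is optimally balanced when its enzymes' FCCs vanish at
  the activity maximum. In the proportional-control regime of a linear
  synthetic chain the three FCCs sum to ≈ 1 (within [0, 1.05] in the
  tests); at balanced points of the canonical batch model the sum exceeds
  1 (up to ~1.3) because the finite-batch endpoint and CrtB's bimolecular
  double-GGPP step sit outside the steady-state summation theorem's
  assumptions.
* **Response curves** evaluate the predictor along a configurable Hill
  induction model (inducer → transcription multiplier; basal, max, K, n).
  The exact published induction model is not public; Hill is the
  conventional choice. With sequestration-prone parameter sets (strong
  product rebinding) the curve rises and then falls — excess enzyme
  lowers productivity by holding intermediates as complexes.
* **Precursor sweeps** report fold-improvement vs supply 1. The
  balanced-vs-bottlenecked comparison is demonstrated with the bottleneck
  at the terminal enzyme (CrtI), whose unimolecular steps are
  precursor-independent; a CrtE bottleneck is *itself* relieved by IPP in
  an elementary mass-action model (its catalytic steps are bimolecular in
  IPP), so the ordering is not expected there.
* **Evolutionary landscapes** draw n ∈ {1,2,3} distinct positions
  uniformly over the 105 RBS nucleotides of the three genes, mutate each
  to a uniform different base, re-predict the three translation rates and
  the productivity, and histogram the ratio to the unmutated pathway.
  `greedy_sequence_ascent` (best single-mutation coordinate ascent)
  locates a sequence-space local optimum from which the
  fraction-decreased property is evaluated. Since the bundled crt coding
  sequences are seeded synthetic stand-ins, landscape conclusions are
  about the model's geometry, not the real operon.
* **Zoom targeting** grid-searches a log-space box (default 10× per gene
  around the current best) and returns per-gene windows containing the
  top-decile predictions, formatted for a Zoom-mode `DesignSpec`; a flat
  landscape returns the expanded box with a warning.

## Numerical and degenerate-input choices

Lexicographic expansion order and seeded `numpy.random.Generator` streams
make every stochastic path reproducible byte-for-byte; GA ties on the
objective break lexicographically. Fill-window boundary ties count as
filled (inclusive comparison with a 1e-9 log-space guard). The bin-count
ceiling is taken after rounding the log-span/W quotient to 9 decimals so
exact multiples do not gain a phantom bin. Edit operators with no eligible
position raise a dedicated no-op error and are redrawn by the GA loop.
Zero enzyme ratios are legal (they zero the flux); negative ratios,
non-positive rates, and empty RBSs are rejected. FCCs at zero
productivity are reported as NaN rather than extrapolated.

## Known limitations

The biophysical model omits translation elongation, codon usage, mRNA
half-life, translational coupling, and structured standby sites; its
spacing/start parameters are plausible defaults, not fitted constants.
The kinetic model omits growth feedback, toxicity, and media effects, and
its precursor boundary assumption makes supply sweeps qualitative. The
published absolute flux-control coefficients and productivities for this
pathway depend on parameter tables and a network realization that are not
bundled here; this package reproduces the structural counts, calibration
identities, and qualitative orderings, not those absolute values.
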