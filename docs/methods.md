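# Methods

## The toy model

The pipeline's study object is a coarse-grained receptor–ligand dimer.
Each chain is a row of residues spaced 4.5 Å apart; a residue carries a
backbone bead (CA, 12 amu) and a sidechain bead (SB, 32 amu), and interface
donor residues add an explicit hydrogen bead (1 amu) so the
donor–H–acceptor geometry of a hydrogen bond exists literally rather than
by proxy. The force field is:

- harmonic bonds E = k/2 (r − r₀)² along the backbone (plus a weak
  second-neighbour stiffener that keeps chains extended), CA–SB and SB–H;
- a Lennard-Jones pair term with Lorentz–Berthelot combination, overridden
  for the aligned interface sidechain pairs (ε = 3.5 kcal/mol, LJ minimum
  at the 2.8 Å reference donor–acceptor distance);
- screened Coulomb (effective dielectric 2, screening length 10 Å) with
  ±0.25 e on donor hydrogens / acceptor sidechains and compensating
  backbone charges, so each interface pair is held by both a van der Waals
  well and an electrostatic hydrogen-bond term.

These strengths were chosen once so that at 310 K the wild-type complex
stays bound (a unimodal bound basin, verified by test) while thermal motion
still breaks and reforms individual interface contacts. The mutant is the
same topology with a declared parameter change only: the middle aligned
residue loses its interface well (ε → 0.05) and its charges, and its two
sequence neighbours are weakened (ε → 1.5, charges × 0.6). This mimics a
single interface-residue deletion perturbing its neighbours without doing
topology surgery; the WT/MUT difference set is machine-enumerable and
tested. The "crystallization clamp" used in the comparative design is a
weak harmonic positional restraint (default 2 kcal/mol/Å²) on the
interface residues of both chains — an external rigidifier standing in for
a bound nanobody, deliberately not a third molecule.

What the toy does **not** emulate: solvent structure, realistic protein
force fields, conformational substates, or any sequence specificity.
Passing tests therefore demonstrate the correctness and internal
consistency of the *methods* (sampling, reweighting, energetics,
fingerprints) and the qualitative comparative logic, not quantitative
properties of the real complex.

## Dynamics

BAOAB-splitting Langevin dynamics, friction 2 ps⁻¹ (the collision
frequency used for the reference all-atom systems), default timestep 5 fs
(the stiffest toy bond has a ~190 fs period), T = 310 K,
k_B = 1.9872×10⁻³ kcal/(mol·K). No barostat, cutoffs or periodicity: the
systems are small enough for exact pair sums. Runs are seeded and bitwise
reproducible. The first 10 % of frames are discarded before analysis by
default (the burn-in rule is configurable; no principled value exists for
the general case).

## GaMD

Boost parameters come from an unbiased pre-stage: E = V_max (the
conservative lower-bound choice; the V_min + 1/k upper-bound variant is
available as an option), k = k₀/(V_max − V_min),
k₀ = min(1, (σ₀/σ_V)(V_max − V_min)/(V_max − V̄)). σ₀ defaults to
6 kcal/mol. This construction guarantees the two defining properties of
the boost — monotonicity (rank order of states preserved) and contraction
(energy differences shrunk) — and caps the predicted boost spread at σ₀,
which is what keeps second-order cumulant reweighting usable; all three
are asserted on sampled parameter sets. During boosted runs forces are
scaled by 1 − k(E − V) below threshold and the per-frame boost is recorded.
Parameters are frozen once production starts.

Reweighting multiplies the biased bin probability p′(RC_j) by the per-bin
average ⟨e^{ΔV/k_BT}⟩_j (estimated either directly via a log-sum-exp, or as
exp(βμ_j + β²σ_j²/2) for the cumulant-2 estimator) and renormalizes over
the occupied bins so that p sums to one; empty bins are excluded from the
normalization and reported as missing rather than extrapolated. Both
estimators are provided because the field uses both; cumulant-2 is the
default, and on a 1-D analytic double well at 310 K either recovers the
Boltzmann profile within 0.5 kcal/mol on bins with ≥ 200 samples (the
acceptance benchmark: 32 walkers × 40 000 steps after a 4 000-step
unbiased stage).

## ABMD

Collective variables are built from four anchor bead groups T, U, W, X:
distance between CoM(T∪U) and CoM(W∪X); the T–U–Y angle with
Y = CoM(W∪X); the T–U–W–X group-centre dihedral. CV gradients chain an
exact centre-weight Jacobian with finite differences over the (≤ 4) centre
points. The flooding bias lives on a node grid over one or two CVs; each
step deposits a biweight (quartic) kernel of half-width 4 grid cells with
energy k_BT·dt/τ (τ is the flooding timescale; the kernel and the k_BT
scale follow the reference flooding scheme since no resolution or τ is
canonical). Deposits outside the grid are rejected (or clipped, by
option), and harmonic walls keep the CV on the grid. Convergence is
declared when consecutive 10 %-length window averages of the bias agree
within 0.2 kcal/mol over the well-flooded region (nodes above 25 % of the
final bias maximum) — unvisited high-F nodes trail the uniform growth of a
converged profile forever and must not veto convergence. The PMF is the
negated bias averaged over the last half of the snapshot history, shifted
to a zero minimum; on a 1-D harmonic CV this recovers the analytic PMF
within 0.3 kcal/mol (500 000 steps, τ = 4 ps).

Binding ΔG integrates e^{−F/k_BT} over disjoint bound and unbound windows
of the separation CV (defaults [3, 8] Å and [12, 18] Å, bracketing the toy
well at ~4.4 Å and the flat tail). No standard-state volume correction is
applied (exposed as future option); for the WT-vs-MUT *difference* the
correction cancels. Replicate spread (std over ≥ 3 seeds) is the quoted
uncertainty; ΔΔG = ΔG_MUT − ΔG_WT with quadrature propagation, and the
K_d fold-change is e^{ΔΔG/k_BT}. Significance of ΔΔG > 0 uses a one-sided
one-sample t-test on per-seed paired differences (a sign-flip permutation
test is included as an alternative; the original analysis names no test).

## End-state energetics

Single-trajectory MM-PBSA-style evaluation: complex, receptor and ligand
terms come from the same frames, so bonded (internal) terms cancel
identically — asserted per frame — and all deltas reduce to cross-chain
contributions. Gas-phase electrostatics is unscreened Coulomb
(332.0637 q₁q₂/r), vdW the LJ pair term. Polar solvation is a pairwise
screened generalized-Born surrogate,
E = −½·332.0637·Σ_ij q_i q_j (1/ε_in − e^{−κf_ij}/ε_out)/f_ij with the
Still interpolation f_ij = √(r² + a_i a_j e^{−r²/4a_i a_j}) and κ the
Debye parameter for the configured ionic strength (default 0.150 M,
reading the stated "0.150 nM" as a typo — sub-nanomolar salt would give a
kilometre-scale screening length) at 310 K. It reduces to the Born
self-energy for an isolated bead, which is the tested limit. A grid
Poisson–Boltzmann solver is deliberately out of scope for bead models; the
surrogate honours the polar term's role and limits. Nonpolar solvation is
γ·SASA with γ = 0.0072 kcal/mol/Å², SASA from Shrake–Rupley sampling on a
deterministic Fibonacci point set (default 960 points; 242 in the bulk
workflow for speed — both within 1 % of dense sampling on the tested
geometries). −TΔS is fixed to zero and flagged "not computed" (no
normal-mode analysis). Per-residue decomposition splits every cross pair
half-and-half between its partner residues and attributes each bead's SASA
change on burial to its own residue; the residue sums reproduce the totals
to 10⁻⁶ kcal/mol exactly by construction.

## Fingerprints

Contacts: residue centre-of-mass distance within (≤) 6 Å, inclusive —
boundary behaviour is fixed so tests are deterministic. Hydrogen bonds:
donor heavy atom within (≤) 3.0 Å of the acceptor *and*
acceptor–H–donor angle ≥ 135°; counts carry per-frame multiplicity.
Subsampling takes every stride-th frame starting at frame 0
(45 000 → 4 500 at stride 10). The HbR table compares mutant/WT
hydrogen-bond count ratios with (HbR1) and without (HbR2) the clamp:
zero denominators give a ratio of 0 by table convention; the flag is
"Yes" iff HbR1 > HbR2 (unrounded), "−" when the mutant counts vanish in
both conditions. Display rounding is decimal **half-down** at 2 decimals,
escalating to 3 when the two ratios collide at 2 decimals while differing
unrounded — the convention that reproduces every row of the published
reference table, including its 0.375 → 0.37 tie. Count-difference
significance uses a two-sided Mann–Whitney U on non-overlapping 10-frame
block means to blunt frame autocorrelation. RMSD uses Kabsch
superposition (via scipy's rotation solver); RMSF aligns frames to the
mean structure and aggregates per-bead variances into mass-weighted
per-residue values.

## Synthetic ensembles

The generator produces geometry-only ensembles (frame energies zero, so
fingerprint results cannot depend on the dynamics engine) with prescribed
per-pair contact and hydrogen-bond probabilities. Each frame jitters all
beads (σ = 0.08 Å), then places each prescribed ligand residue rigidly and
*exactly* inside or outside its criterion: contacts at CoM distances
4.0–5.6 Å (hit) or 7.0–9.5 Å (miss); hydrogen bonds by solving the
donor–H–acceptor triangle for an exact target distance of 2.6–2.9 Å at
angles 155–180° (hit) or a collinear 3.3–4.5 Å placement (miss). A ligand
residue may appear in at most one prescription, keeping placements
independent, so the empirical frequencies are exact binomial draws — the
recovery tests check them against 3 binomial standard errors.

## Numerical and design notes

- Coinciding beads raise an explicit singularity error rather than NaNs;
  NaN forces abort a run.
- Reaction-coordinate binning treats the top bin edge as inclusive.
- Bins with a single sample get a zero cumulant variance and a
  low-confidence flag.
- ABMD is not run on clamped variants in the bulk workflow: positional
  restraints suppress dissociation along the separation CV, making that
  PMF meaningless; clamped variants enter the comparison through
  fingerprint difference maps, which is where the attenuation claim lives.
- The 2-D (native contacts × H-bond count) GaMD-vs-unbiased consistency
  test uses a weakly clamped mutant because it interconverts between
  interface states fast enough for two independent runs to agree; the free
  dimers' binding/unbinding transitions are too slow for that comparison
  at desk scale.
- Problem sizes throughout (5×4-residue dimers, 10⁴–10⁵-step stages,
  3 seeds) are chosen as the smallest at which every qualitative claim is
  stable across seeds; they are study-design constants, not tunables.

## Known limitations

The toy ΔG values are not comparable in magnitude to any real
protein–protein system; only signs and orderings are meaningful. The GB
surrogate has no dielectric boundary, so its absolute polar energies are
heuristic. Flooding PMFs on the rough toy landscape converge slowly; the
replicate spread of ΔG_ABMD is large and only the paired WT-vs-MUT
difference is robust. The HbR display convention is inferred from the
printed table's rounding behaviour and is a rendering choice, not
statistics.
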