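# Methods

This note records the model as implemented, the conventions chosen where
more than one reasonable reading exists, and what the synthetic test
configurations do and do not establish about real aggregation data.

## Force field

Beads: backbone (B), side chain (S), N-terminal cap (TN), C-terminal cap
(TC); an n-residue chain has 2n + 2 beads.  Units are GROMACS-style
throughout (nm, kJ/mol, amu, ps; k_B = 0.008314462618 kJ mol⁻¹ K⁻¹).

**Bonds** are harmonic, V = ½ k_b (r − r₀)², in the GROMACS/MARTINI
convention (the ½ lives in the potential, not in k_b).  B–B and B–T bonds:
k_b = 1250 kJ mol⁻¹ nm⁻², r₀ = 0.35 nm.  B–S bonds: k_b = 5000 kJ mol⁻¹
nm⁻², with r⁰_BS a scanned parameter (0.40–0.70 nm).

**Angles** use the cosine-harmonic form V = ½ k_θ (cos θ − cos θ⁰)² with
k_θ = 1000 kJ/mol, θ⁰_BBB = 150°, θ⁰_BBS = 105°.  The cosine form is the
MARTINI convention and is consistent with k_θ being quoted in kJ/mol
(dimensionless argument) rather than kJ mol⁻¹ rad⁻²; a harmonic-in-angle
form is available via `ForceField.angle_form = "harmonic"`.  Angle
assignment: one BBB angle per interior backbone triplet, and one BBS angle
between each side chain S_i and every *existing* backbone neighbour of B_i
— two for interior residues, one at the chain ends, giving 2(n−1) BBS
angles per chain.  Caps take part in no angle terms.

**Nonbonded** pairs interact through 12-6 Lennard-Jones, excluded only for
directly bonded pairs (1-3 pairs and beyond do interact — this is a model
feature, not an oversight; the stiff angles do the job of torsional
restraints).  The pair matrix: ε_BB = 4.5, σ_BB = 0.47; ε_BS = 2.0,
σ_BS = (σ_BB + σ_SS)/2 (Lorentz arithmetic mean; configurable); ε_SS = 1.0
with σ_SS scanned (0.37–0.45 nm); every cap pair uses σ = 0.40 with
ε_BT = ε_ST = 0.5; opposite caps attract with ε = 4.0; identical caps
(TN–TN, TC–TC) interact through a purely repulsive V = 4ε(σ/r)¹² with
ε = 4.0 — the natural "LJ with the attractive coefficient zeroed"
realization; a WCA variant (LJ cut-shifted at 2^{1/6}σ) is available via
`repulsive_form = "wca"`.

**Truncation.**  All nonbonded interactions are cut at 1.2 nm and shifted
so the potential is continuous (zero) at the cutoff.  The cutoff scheme is
our choice (the protocol leaves it open); 1.2 nm is the conventional radius
for force fields of this resolution and is ≥ 2.5 σ for every pair.  Raw
(untruncated) scalar potentials are retained for unit testing.

**Masses.**  72 amu for every bead (the standard four-heavy-atom
coarse-grained mass).  Masses only set the time scale of the Langevin
dynamics and cancel from all structural and kinetic observables reported
here; the value is configurable.

Forces are the exact analytic negative gradient of the implemented
(shifted) energy; the test suite checks them against central finite
differences with step 10⁻⁶ nm.  All distances, including bonded ones, use
the minimum-image convention, making the energy invariant under whole-box
shifts of any bead.

## Dynamics

The integrator is Langevin leapfrog in the BAOAB splitting: half kick, half
drift, exact Ornstein–Uhlenbeck velocity refresh
(v ← a v + √((1−a²) k_B T/m) ξ with a = e^(−dt/τ)), half drift, half kick.
Friction is parameterized GROMACS-style by the inverse friction coefficient
τ = 0.17 ps, i.e. per-bead γ = m/τ; this reading of "inverse friction
coefficient" as a time constant matches the implicit-solvent protocol.
Defaults: dt = 15 fs, T = 303 K, cubic periodic box L = 35 nm.

Useful limits, each verified by a test: τ → ∞ recovers symplectic velocity
Verlet (two-bead bond energy drift < 0.1% over 10⁴ steps at dt = 2 fs);
T = 0 gives geometric velocity decay; for non-interacting beads the O-step
is exact, so the ideal-gas kinetic temperature is unbiased at any dt.
Velocities are initialized from the Maxwell–Boltzmann distribution with a
seed stream spawned separately from the thermostat noise; trajectories are
bit-reproducible given (frame, settings).

Coordinates are stored unwrapped; `Frame.wrapped()` is provided for export.
Random placement inserts straight equilibrium-geometry chains with uniform
random position/orientation and a 0.5 nm inter-chain floor (rejection
sampling with a periodic k-d tree).

The straight-chain template is exact: the backbone is a planar zigzag whose
bond directions alternate ±15° about the chain axis (every BBB angle
exactly 150°), and each side chain sits on the in-plane external bisector
of its vertex — because 105° = (360° − 150°)/2, both BBS angles of an
interior residue are exactly 105° simultaneously, so the template is the
exact minimum of the bonded energy.

**Minimization** is steepest descent along the force with Barzilai–Borwein
step control and halving backtracking; steps that would raise the energy
are rejected, so the energy is non-increasing.  Convergence criterion: the
largest force component below `tol` (default 1 kJ mol⁻¹ nm⁻¹; the
geometry-recovery experiments use 10⁻⁴).

## Cluster analysis

Two peptides are linked when any bead of one (side-chain and cap beads
included; configurable) is within 5.5 Å of any bead of the other, minimum
image, boundary inclusive.  Clusters are connected components of the link
graph (single linkage), computed from a periodic k-d tree
(`scipy.spatial.cKDTree` with `boxsize`) — the standard cell-list-style
neighbour search — with an all-pairs minimum-image brute-force path kept as
the test oracle; the two agree exactly on randomized configurations.  The
kinetic observables are n₁, n₂, n₃ (monomer, dimer, trimer counts) and
n_c = Σᵢ nᵢ (clusters of every size, monomers included).  Across repeat
trajectories, repeats are aligned to the first repeat's time grid by
nearest-frame matching and reported as mean ± standard deviation of the
mean.

## Order parameters

**C_n** (directional order): with n̂ᵢ the normalized first-to-last backbone
B-bead vector of peptide i (caps and side chains excluded),

    C_n = 1/(M(M−1)) Σ_{i≠j} (n̂ᵢ·n̂ⱼ)².

The squared dot product makes the measure head/tail blind, as it must be
for a motif built on antiparallel pairing: identical, antiparallel or mixed
alignments all give exactly 1, while isotropically random orientations give
E[(n̂·n̂′)²] = 1/3 — consistent with the stated limiting values (1 for
parallel chains, ≈ 0.3 for random).  This pairwise-squared form was chosen
over the nematic Q-tensor eigenvalue (which gives 0, not 1/3, for random
orientations); the Q-tensor variant can be swapped in if a different
normalization is wanted.

**C_BB** (positional order): for each peptide i, neighbours are peptides
whose backbone mass centres lie within 0.8 ≤ r ≤ 2.4 nm of peptide i's
centre.  For each unordered pair (j, k) of distinct neighbours, take
|û_ij·û_ik| with û the unit centre-to-centre vectors; average over pairs,
then over all peptides with ≥ 2 neighbours (peptides with fewer do not
contribute; if none contributes, C_BB is undefined and flagged as NaN).
The absolute value (rather than the square) is a reconstruction choice:
collinear ribbon stacking gives exactly 1 and orthogonal neighbour
directions exactly 0, the two calibration points the definition must hit.
Backbone centres are mass-weighted over B beads on the unwrapped chain
image, so chains straddling the periodic boundary are handled correctly.

**Phase regions.**  The default (C_n, C_BB)-plane boundaries are *fitted to
this package's synthetic fixtures, not to any reference data set*, and are
flagged as assumptions in the configuration: single-ribbon if C_BB ≥ 0.8;
multi-ribbon/annular if C_n ≥ 0.6 and C_BB ≥ 0.5; amyloid-glass if
C_n ≥ 0.4 or C_BB ≥ 0.4; otherwise amorphous.  Rules are evaluated in that
order, so boundary ties resolve toward the more ordered label.  Any
quantitative phase assignment on real trajectories should re-derive these
thresholds from its own reference structures.

## Aggregation–fragmentation kinetics

Clusters interconvert through C_i + C_j ⇌ C_{i+j} in a closed system of N
chains in volume V (no sources or sinks; sizes truncated at N, which costs
nothing because total mass is N).  Rate constants follow the
three-parameter rule: k⁺ and k⁻ for all channels, both multiplied by q for
any channel involving a monomer (k⁺₁ⱼ = qk⁺ *and* k⁻₁ⱼ = qk⁻ — scaling
forward and backward together is what keeps every channel's equilibrium
constant at k⁺/k⁻ and hence preserves detailed balance).

**Conventions.**  The aggregation flux of channel (i, j) is k⁺ᵢⱼ c̄ᵢ c̄ⱼ
for i ≠ j and k⁺ᵢᵢ c̄ᵢ²/2 for i = j (the pair count of identical clusters).
Symmetry then forces the fragmentation side: an unordered channel (j, k)
fragments at rate k⁻ⱼₖ c̄ᵢ for j ≠ k and k⁻ⱼⱼ c̄ᵢ/2 for the equal split.
The halved equal-split rate is not optional: a Kolmogorov cycle test on the
N = 4 partition graph (22 → 4 → 31 → 211 → 22) shows that full-rate equal
splitting combined with the c̄²/2 aggregation convention violates detailed
balance by a factor of 4, while the symmetric convention satisfies it
exactly — at the mean-field level (stationary channel residuals at solver
precision, ~10⁻¹⁵ relative) and at the master-equation level (the
stationary distribution passes the per-transition flux-balance test).  A
corollary worth knowing: the equilibrium state is independent of q
entirely, since q cancels within each monomer channel.

With ordered sums over (j, k), the implemented rate equations read

    dc̄ᵢ/dt = ½ Σ_{j+k=i} k⁺ⱼₖ c̄ⱼc̄ₖ − c̄ᵢ Σ_{j ≤ N−i} k⁺ᵢⱼ c̄ⱼ
              − ½ Σ_{j+k=i} k⁻ⱼₖ c̄ᵢ + Σ_{k ≤ N−i} k⁻ᵢₖ c̄_{i+k} ,

which conserve Σ i c̄ᵢ identically (verified to 10⁻¹⁵ on random states).
They are integrated with LSODA at rtol 10⁻⁸; cluster numbers are nᵢ = c̄ᵢV.
A stationary-state solver (long relaxation + Newton polish under the mass
constraint) supports the detailed-balance diagnostics.

**Stochastic counterpart.**  The Gillespie SSA uses the exact propensities
k⁺ᵢⱼ mᵢmⱼ/V (i ≠ j), k⁺ᵢᵢ mᵢ(mᵢ−1)/(2V), and k⁻ⱼₖ m_{j+k} (halved for
j = k), with mass conserved exactly at every event and the event sequence
thinned onto a fixed sample grid.  For N ≤ 10 the master equation over
integer partitions (42 states at N = 10) is solved exactly and serves as
the oracle for the SSA means; at N = 72 the SSA ensemble mean and the ODE
solution agree to ~1% of N over the full 12 μs window, quantifying the
(small) mean-field error at this system size.

**Fitting.**  The global fit minimizes the plain sum of squared differences
over the four curves (n₁, n₂, n₃, n_c) and all time points — equal weights,
since the protocol gives no weighting rule; per-curve weights are
accepted as an option.  The optimizer is Nelder–Mead on log(k⁺, k⁻, q)
(positivity by construction), with five starts: the user's guess plus four
log-normal perturbations (σ = 0.3) drawn from the fit seed.  Sampling grid
for the synthetic-recovery experiments: 10 ns spacing over 0–600 ns (the
fast monomer-depletion phase) and 100 ns spacing over 0.6–12 μs (the slow
coarsening tail that pins down k⁻), 175 points total.

## Synthetic-recovery experiments and their scope

The acceptance experiments (also `scripts/acceptance.py`) generate 1000 SSA
repetitions at a reference parameter set from the amorphous regime
(k⁺ = 7.84 nm³/ns, k⁻ = 10.69×10⁻⁵ ns⁻¹, q = 3.07, N = 72, V = (35 nm)³),
average them, and refit from the deliberately wrong guess (5.0, 2×10⁻⁴,
2.0).  Across seeds the recovered parameters land within ~6% of the
generating values; k⁺ comes back slightly low and q slightly high in a
correlated way, which is the mean-field bias at N = 72, not an optimizer
artefact (the noiseless ODE self-fit recovers all three to < 0.1%).
Fragmentation is the weakest-identified parameter — it only shapes the
late plateau — hence its wider tolerance.

What these experiments establish: the estimator pipeline (SSA → averaging →
global least squares) is consistent and nearly unbiased *when the data are
generated by the kinetic model itself*.  They do not establish that the
three-parameter model describes any particular molecular trajectory; on
real (or simulated-MD) cluster counts the model is an approximation whose
fit quality degrades for strongly ordered aggregates, and the fitted cost
should be inspected, not assumed small.

Similarly, the geometry fixtures (parallel ribbon, antiparallel pair,
annular ring, random gas, amorphous blob) are idealized calibration
configurations: they pin the order parameters' limiting values and the
classifier's corner behaviour, but passing them says nothing about
thermally disordered aggregates beyond those limits.

## Numerical details and edge cases

- Degenerate (zero-length) end-to-end vectors raise, naming the peptide.
- C_n needs M ≥ 2 and C_BB at least one peptide with two shell neighbours;
  otherwise NaN, and classification returns "unclassified".
- Pair distances below 0.05 nm flag the frame as overlapping (energy still
  returned); non-finite coordinates abort dynamics naming the step.
- Cluster search falls back to the brute-force path when the cutoff is not
  below L/2 (tiny boxes), where the periodic tree is invalid.
- SSA sampling records the pre-event state for sample times coinciding
  exactly with an event time.
- The bonded-geometry recovery experiments perturb all bead positions with
  Gaussian noise of 0.03 nm — large enough to displace every angle and
  bond, small enough to stay in the template's basin.
- Aggregation smoke runs use 8 chains in an L = 6.5 nm box (≈ 2.8× the
  reference monomer density) so that first contacts occur within ~1 ns of
  simulated time.

## Known limitations

- No electrostatics, dihedrals, or directional hydrogen-bond terms, and no
  solvent particles: by design, this model class asks what the *absence*
  of directional interactions still permits.
- Energies/forces use dense pair lists (fine to a few thousand beads);
  production-scale campaigns (tens of μs, many repeats) are out of scope.
- The phase boundaries are fixture-calibrated defaults, not measured ones.
- The kinetic model assumes well-mixed kinetics with size-independent rate
  constants apart from the monomer factor q; diffusion-limited kernels or
  size-dependent fragmentation are not implemented.
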