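# twobead

A minimal two-beads-per-residue implicit-solvent peptide model for studying
how side-chain geometry controls aggregate morphology — from amorphous blobs
through amyloid-glasses to fibrils and annular (pore-like) structures — and
for modelling the aggregation kinetics with a three-parameter
coagulation–fragmentation rate model.

The package is aimed at coarse-grained modellers who want a desk-scale,
fully scriptable re-implementation of this model class: the force field and
Langevin dynamics that generate aggregation, the cluster and order-parameter
analyses that classify aggregate morphology, and the kinetic model with its
exact stochastic counterpart and global fitter.

## The model

Each residue of a homopeptide is represented by a backbone bead **B** and a
side-chain bead **S**; the chain ends carry terminal caps **TN** / **TC**
(an n-residue chain is 2n + 2 beads).  Interactions are deliberately
minimal — no dihedrals, no electrostatics, no directional hydrogen-bond
terms:

- harmonic bonds, V = ½ k_b (r − r₀)²: backbone and cap bonds with
  k_b = 1250 kJ mol⁻¹ nm⁻², r₀ = 0.35 nm; a stiff B–S bond with
  k_b = 5000 kJ mol⁻¹ nm⁻² whose equilibrium length **r⁰_BS ∈ [0.40, 0.70] nm
  is a scanned parameter**;
- cosine-harmonic angles, V = ½ k_θ (cos θ − cos θ⁰)², with k_θ = 1000 kJ/mol,
  θ⁰_BBB = 150°, θ⁰_BBS = 105°;
- Lennard-Jones pair potentials between all non-bonded beads, with a strong
  backbone–backbone attraction (ε_BB = 4.5 kJ/mol, σ_BB = 0.47 nm), weaker
  B–S (2.0) and S–S (1.0) attractions, and the **side-chain radius
  σ_SS ∈ [0.37, 0.45] nm as the second scanned parameter**
  (σ_BS = (σ_BB + σ_SS)/2);
- purely repulsive r⁻¹² interactions between identical termini and a strong
  attraction (ε = 4.0) between opposite termini, mimicking zwitterionic
  capping.

Dynamics is Langevin (BAOAB leapfrog) at 303 K with a 15 fs step and
friction time constant τ = 0.17 ps, in a cubic periodic box (reference
system: 72 octapeptides, L = 35 nm).  The two scanned parameters set the
side-chain geometry, which is what tips the aggregates between amorphous,
glassy, fibrillar and annular morphologies.

**Analysis.**  Peptides within 5.5 Å of each other (any bead pair, minimum
image) belong to one cluster (single linkage).  Two cluster descriptors
classify morphology: the end-to-end correlation parameter
C_n = ⟨(n̂_i·n̂_j)²⟩_{i≠j} (1 for parallel/antiparallel alignment, 1/3 for
random orientations) and the backbone–backbone correlation parameter C_BB,
the average |cos| between directions from a peptide's backbone centre to its
neighbours in the 0.8–2.4 nm shell (1 for ribbon stacking, ~0.5 for a
random shell gas).

**Kinetics.**  Cluster populations follow modified Smoluchowski
coagulation–fragmentation equations for C_i + C_j ⇌ C_{i+j} with three
parameters: an aggregation rate constant k⁺ (nm³/ns), a fragmentation rate
constant k⁻ (ns⁻¹), and a ratio q by which both monomer attachment *and*
detachment are faster — a choice that preserves detailed balance exactly.
The package solves the mean-field ODEs, runs the exact Gillespie stochastic
counterpart, solves the master equation exactly for small systems, and
globally fits (k⁺, k⁻, q) to observed monomer/dimer/trimer/total-cluster
curves by least squares.

## Worked example

```python
import numpy as np
import twobead as tb
from twobead.kinetics import (KineticParameters, monomer_start,
                              gillespie_ensemble, fit_kinetics)

# --- structure: a 12-chain annular (pore-like) aggregate -------------------
ff = tb.default_forcefield(sigma_SS=0.39, r0_BS=0.70)
frame, top = tb.make_fixture(tb.FixtureSpec(kind="annular_ring", n_chains=12), ff)
clusters = tb.find_clusters(frame, top)          # -> one cluster of 12
d = tb.describe_cluster(frame, top, clusters.members(0))
print(f"C_n = {d.c_n:.3f}, C_BB = {d.c_bb:.3f}")  # C_n = 1.000, C_BB = 0.627
print(tb.classify_phase(d))                       # multi-ribbon/annular

# --- kinetics: stochastic ensemble and a global fit ------------------------
params = KineticParameters(k_plus=7.84, k_minus=10.69e-5, q=3.07, N=72, V=35.0**3)
t = np.linspace(0.0, 12000.0, 150)                # ns
curves = gillespie_ensemble(params, monomer_start(72), t, 200, seed=8)
print(curves.mean["n1"][-1], curves.mean["nc"][-1])   # 0.52, 6.50
guess = KineticParameters(k_plus=5.0, k_minus=2e-4, q=2.0, N=72, V=35.0**3)
fit = fit_kinetics(curves, guess, n_starts=3, seed=0)
print(fit.params)   # k+ = 7.63 nm^3/ns, k- = 11.19e-5 ns^-1, q = 3.17
```

The annular fixture scores perfect directional order (C_n = 1: its chains
form antiparallel pairs) with intermediate positional order (C_BB ≈ 0.63:
neighbour directions curve around the ring), landing in the
multi-ribbon/annular region of the phase plane.  The kinetic fit recovers
the generating parameters to within a few percent from a deliberately wrong
starting guess; the residual bias is the mean-field error of the rate
equations at N = 72.

A command-line interface mirrors the library
(`twobead simulate|minimize|clusters|curves|order|classify|ssa|odefit|fixture`);
`twobead --show-assumptions` lists every default the model itself does not fix.

## Layout

- `src/twobead/forcefield.py`, `topology.py`, `system.py` — parameters,
  bead graph, energies and analytic forces
- `src/twobead/dynamics.py` — Langevin integrator, minimizer, system setup
- `src/twobead/clustering.py`, `order.py` — cluster census and morphology
  descriptors
- `src/twobead/kinetics.py` — rate equations, Gillespie SSA, master
  equation, fitting
- `src/twobead/fixtures.py`, `io.py`, `config.py`, `cli.py` — generated
  reference configurations, GRO/XYZ/CSV formats, configuration, CLI
- `docs/methods.md` — model details, conventions and numerical choices
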