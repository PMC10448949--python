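# Methods

This note documents the models, numerical choices, and design decisions
behind `modefit`, and states what the synthetic benchmark does and does not
demonstrate.

## Structure model

Structures are chain → residue → heavy-atom hierarchies with author
numbering (insertion codes kept). On reading PDB/mmCIF (via gemmi),
hydrogens and waters are dropped, alternate locations collapse to the
highest-occupancy copy (first on a tie), and only the first model of
multi-model files is used: every distance cutoff in the pipeline is defined
over heavy atoms, and altloc handling in deposited structures is not
standardized, so a single deterministic convention is applied everywhere.
Polymer type is a pure function of the residue name (20 standard amino
acids → protein; DA/DC/DG/DT → dna; A/C/G/U → rna; everything else →
other). Nonstandard residues are kept and participate in distance-based
metrics, but not in sequence alignment.

## Evaluation metrics

CAPRI conventions: the native interface is every residue with ≥1 heavy atom
within 10.0 Å of the other subunit; native contacts use 5.0 Å; f_nat is the
recovered fraction of those contacts; I-RMSD superposes native-interface
backbone atoms onto the model; L-RMSD superposes receptors and reports the
ligand backbone RMSD with no further fitting. A model is acceptable when
f_nat ≥ 0.10 and (I-RMSD ≤ 4.0 Å or L-RMSD ≤ 10.0 Å). Backbone atom sets
are N, CA, C, O (protein) and P, O5', C5', C4', C3', O3' (nucleic) — the
standard CAPRI/DockQ choice. L-RMSD is backbone-only by default with an
all-heavy-atom flag, since conventions differ between assessors. Missing
backbone atoms drop the atom pair, not the residue. Unbound↔bound residue
correspondence uses global alignment (BLOSUM62, gap −11/−1 for protein;
+1/−1 identity, −2/−1 gaps for nucleic); superposition is least-squares
(SVD with reflection excluded), cross-checked in the tests against an
independent quaternion implementation.

## Elastic network and RTB reduction

The deformation model is an anisotropic network over all heavy atoms:
harmonic springs on every pair within 15.0 Å of the input conformation,
uniform spring constant γ = 1 (constants cancel in mode directions, which
are all the fitting uses). The Hessian has off-diagonal super-elements
−(γ/s⁰²)·d dᵀ and diagonal blocks equal to minus the row sums, so the six
rigid-body motions span its null space exactly; this is verified against a
central-finite-difference Hessian of the pair potential in the tests.

Diagonalization goes through an RTB projection with one block per residue:
each block contributes its three translations and up to three rotations
about the block centroid, orthonormalized per block (degenerate blocks —
single atoms, collinear atoms — fall back to fewer columns). The reduced
matrix PᵀHP is diagonalized densely (reduced problems here are ≤ a few
thousand degrees of freedom), eigenvalues below 1e-6 × λ_max are discarded
as rigid-body, eigenvectors are expanded through P and re-orthonormalized,
and each mode's sign is fixed (first significant component positive) so
runs are bit-reproducible. Twenty modes are used for fitting.

RTB is a Rayleigh–Ritz restriction: reduced eigenvalues can only
overestimate, and the approximation sharpens with system size. On the
232-atom hinge benchmark the three lowest RTB modes overlap the full-ANM
modes at ≥ 0.999 with eigenvalue errors under ~11%. On very small systems
(tens of atoms) with near-degenerate spectra, mode-by-mode agreement is not
meaningful and is not claimed.

## Restraint field and minimization

The per-iteration minimization intentionally carries no long-range physics:
its only job is to keep covalent geometry sane while the modes do the
moving. Terms, all referenced to the *input* conformation:

- bonds: k(ℓ−ℓ₀)², k = 100, pairs detected at < 1.8 Å;
- angles: k(θ−θ₀)², k = 20, over bonded triples;
- clashes: k·max(0, 2.8 − d)², k = 50, over pairs not excluded as 1-2/1-3;
  pairs already inside 2.8 Å in the reference are grandfathered so the
  input geometry is exactly stationary;
- peptide-plane tethers: CA(i)–CA(i+1) virtual bonds (k = 100). In a
  backbone-only model nothing else penalizes an ω flip to cis, which would
  let the chain crumple at zero cost;
- hydrogen-bond tethers: N···O pairs ≥ 3 residues apart within 3.5 Å
  (k = 10), a coarse-grained stand-in for the secondary-structure
  H-bond network that all-atom packing would otherwise maintain.

Minimization is L-BFGS with analytic gradients, capped at 50 iterations per
fitting cycle, with the clash pair list frozen per call (appropriate for
sub-ångström per-cycle motion). Energy is non-increasing by construction.

## The fitting loop

Iteration 0 rigidly superposes the whole unbound ligand onto the union of
the two domain poses' mapped atoms. Each subsequent iteration: rebuild
ANM+RTB modes on current coordinates; form the displacement field to the
poses (zero on atoms outside the domains — linker atoms move only through
mode components and minimization); project onto the 20 modes; apply the
reconstruction scaled so no atom moves more than 0.5 Å; minimize.

Because the applied step is a positive multiple s ∈ (0, 1] of the projection
of the residual, the RMSD to the domain poses cannot increase at the mode
step (‖Δ − sPΔ‖ ≤ ‖Δ‖); minimization may trade up to ~0.05 Å per iteration
of fit for stereochemistry, and that tolerance is what the tests assert.

The receptor is *absent* from the regular (microcycle) minimization: the
ligand may sweep through its volume while the hinge closes. Steric
complementarity with the receptor is enforced on the macrocycle schedule —
a joint ligand+receptor minimization (receptor mobile) every 10th iteration
after the 100th — and by one final ligand-only minimization against the
fixed receptor after the loop, which clears residual overlap when the run
converges before the first macrocycle. This split matters: with receptor
clash forces active every iteration, fits whose closing path crosses the
receptor's position wedge against it and stall several ångströms short.

Termination: 500 iterations, a wall-clock budget (4 h default), or
convergence — improvement in RMSD-to-domains below 0.01 Å (0.002 Å in the
shipped analysis configs) over a 20–30 iteration window. Identical inputs
and seed give bit-identical trajectories.

## Consensus scoring

Per-pose features: shape score and cluster size from the docking stage
(greedy clustering at 4.0 Å pose RMSD in the fixed receptor frame, no
re-superposition — the standard docking convention); optional external
knowledge-based potentials as named numeric columns; six BSC terms
(occupancy of each residue = number of poses in which it interacts at
cutoff y ∈ {5, 10} Å, summed over the residues interacting in the specific
model, for sides receptor/ligand/both); and the three lowest z-scores among
the pose's standardized features (order statistics). Standardization uses
the population σ over the pool; zero-variance features map to z = 0, which
makes the combined score exactly invariant to raw-feature rescaling.

The logistic combiner's coefficients are not fixed by the method, so the
package ships three routes: load weights from YAML; train by L2-regularized
maximum likelihood (deterministic lbfgs) on labeled decoys; or call
`train_default_scoring_model`, which does exactly that on the synthetic
benchmark at a fixed seed. Complex-level models inherit their BSC terms
from the two constituent domain poses (arithmetic mean by default;
sum/max selectable) rather than recomputing them; order statistics and
standardization are redone over the complex pool.

## Synthetic benchmark

`fixtures` generates the study system: a backbone-only (N, CA, C, O)
poly-alanine chain of two ideal α-helical domains (φ/ψ = −57/−47°) joined
by an extended linker (−120/140°), built by natural-extension-reference-
frame placement from ideal bond lengths and angles, with ±0.5° seeded
dihedral jitter. Defaults — 24 residues per domain, 10-residue linker,
160° hinge budget — were chosen once to land the unbound→bound difference
at ~11 Å Cα, the regime the method targets (real cases in this class run
~10–19 Å).

The bound state applies the hinge **in torsion space**: the budget is
distributed evenly over the linker's φ/ψ dihedrals (sign chosen to avoid
domain collision), so every bond length, bond angle, and domain-internal
coordinate is exactly preserved and the bound state is reachable by bonded
deformation. An earlier construction that rigidly rotated domain 2 and
interpolated the linker by fractional rotations was rejected: per-residue
fractional rotation stretches linker junction bonds by up to ~3 Å, creating
a ground truth no bonded model can reach. That variant remains available
when an explicit hinge axis is requested.

The receptor is a rigid toy double helix (two antiparallel strands, rise
2.8 Å, twist 33°, P/C4'/N1 pseudo-atoms, RNA-typed residues), slid along
the bound ligand's principal axes to the contact-maximizing placement with
a 3.2 Å closest approach. Decoy pools perturb the native domain placement
by N(0, 3°) rotations and N(0, 1 Å) translations (near-native) or place the
domain at random clash-free, clearly-wrong (> 8 Å RMSD) locations around
the receptor; synthetic shape scores decrease linearly with RMSD-to-native
plus seeded noise so the scorer has learnable signal. CAPRI labels on
decoys are recomputed from scratch with the evaluation stack.

What the benchmark does **not** emulate: side chains and packing, real
nucleic-acid geometry and electrostatics, sequence-specific recognition,
domain-internal backbone deformation, and experimental-structure artifacts
(missing atoms, altlocs in anger, nonstandard residues at interfaces).
Passing tests demonstrate the algorithmic machinery — mode projection,
restraint maintenance, metric correctness, scoring algebra, ranking — not
accuracy on experimental complexes.

## Analysis problem sizes

The shipped analyses run at desk scale: flex-fitting-to-native on the
58-residue hinge (232 atoms, converging in ~80 iterations), and the
end-to-end pipeline on 5×5 pose pools (one planted near-native pose per
domain) over a 25-residue hinge at 40 iterations per pair. Production
defaults remain at the method's native scale (50,000-pose truncation, 100
poses per domain, 10,000 pairs, 500 iterations / 4 h per pair).

## Known limitations

- The linker carries no data constraint, so its fitted path is whichever
  bonded conformation the modes and minimizer produce; with long linkers
  the recovered linker can deviate from the generator's ground-truth path
  even when both domains land correctly.
- Domains accumulate ~1 Å of internal plastic deformation in transit
  (torsions are unrestrained between reference-geometry terms); recovery
  below ~1 Å Cα should not be expected.
- Because the receptor exerts no force during microcycles, a closing path
  that crosses the receptor can occasionally leave the chain threaded
  through it; local minimization cannot untangle such a state. Any
  pipeline built on local minimization shares this failure mode.
- The greedy clustering and BSC computations are O(pool²) and O(pool ×
  atoms) respectively; they are fine at the 10⁴–10⁵ pose scale but are not
  engineered beyond it.
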