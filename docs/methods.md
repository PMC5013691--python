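# Methods

## Coarse-grained model

Each residue is a single particle at its Cα position with a uniform mass of
100 Da (the average amino-acid mass). Interactions are hookean springs with
the convention

    V(x) = Σ_pairs K_ij (d_ij − d⁰_ij)²

— note the absence of the conventional ½: a pair stretched by δ pulls each
bead with force 2Kδ, and the Hessian eigenvalue of an isolated spring is
4K. All printed constants assume this convention.

Spring constants follow a two-regime, essential-dynamics-style rule built
from a single reference structure:

* **sequential** (same chain, author numbering gap-free, separation
  s ≤ n_seq = 3): K = c_seq/s² with c_seq = 60 kcal·mol⁻¹·Å⁻². These stiff
  springs preserve backbone stereochemistry.
* **long-range** (every other pair within the 12 Å cutoff):
  K = ε(c/d⁰)^p with ε = 6 kcal·mol⁻¹·Å⁻², c = 6 Å, p = 6, an inverse-power
  decay with the exponent exposed as a parameter.

A pair across a chain break or a numbering gap is demoted to the long-range
rule: springs across breaks should not inherit backbone stiffness. All six
constants are package configuration (CLI flags); none of the shipped tests
depends on their exact values, only on the structure of the rule.

The network's equilibrium lengths d⁰ are read off the build structure, so
V = 0 exactly there; the analytic Hessian at that geometry consists of
rank-one blocks 2K·ûûᵀ per spring.

## Langevin thermostat

Dynamics follow m r̈ = F − γ m ṙ + ξ with Gaussian white noise obeying the
fluctuation–dissipation relation ⟨ξξ′⟩ = 2γ m k_B T δ. Units are Å, fs,
Da, kcal·mol⁻¹ (k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹); γ is given in ps⁻¹
with default 50 ps⁻¹ (solvent-like damping), temperature defaults to
300 K, Δt to 1 fs.

The integrator is the BBK discretization of velocity Verlet with **one**
random force per step entering both half-kicks. For a free particle this
variant reproduces the target kinetic temperature exactly at any γΔt (the
variant with independent noise in each half-kick runs cold by a factor
1/(1+γΔt/2)); residual harmonic-mode error is O(ω²Δt²), negligible at the
stiffest network frequencies (ωΔt ≈ 0.03). The inner loop is JIT-compiled
with numba when available; the pure-Python fallback is the same code body,
so results are bit-identical across both paths. Noise for a block of n
steps is drawn up front from a `numpy.random.Generator`, making an n-step
block bitwise equal to n single steps under the same seed.

Velocities are initialized from the Maxwell–Boltzmann distribution.
Energy/temperature sanity is enforced per block; a divergence raises an
error naming the step.

## Demon-biased transition sampling

The progress variable toward the target is the squared mismatch of
internal distances,

    Γ = Σ_(i,j)∈P (d_ij − d_ij^target)²   [Å²],

with P all corresponded pairs by default or an explicit subset for partial
targets (the network and the dynamics never need the target's missing
regions; only Γ and the convergence measure see the target at all). Γ is
rigid-motion invariant, so no superposition enters the bias.

Every cycle the engine runs k unbiased steps and the demon compares Γ with
the value at the **last accepted checkpoint**: strictly smaller ⇒ accept
(record a frame), otherwise coordinates *and* velocities are restored to
the checkpoint while the noise stream keeps advancing, so each retry
explores a fresh random branch. Ties are rejected to prevent stagnation at
plateaus. Accepted-checkpoint Γ is therefore strictly decreasing by
construction. The run converges when the rMSD to the target (optimal
superposition, restrained residues only if a subset is given) falls within
the thermal-oscillation range: 1.5 Å by default, 3.0 Å above 1000 residues.

**Choice of k (default 300).** At solvent-like friction the network's soft
modes are heavily overdamped; their positional decorrelation times are far
longer than a few hundred femtoseconds. k controls how far the soft modes
can diffuse between demon decisions: too small and the ratchet stalls
against the thermal noise floor of Γ (each accepted checkpoint "freezes" a
fortuitously low fast-mode configuration that short retries cannot beat);
larger k widens the sampled corridor at higher cost per cycle. k = 300
steps makes the toy-hinge transitions converge robustly in both directions
within a few thousand cycles; k remains fully exposed, and the suite
verifies that the perpendicular PC2 excursion grows monotonically with
k ∈ {10, 100, 1000}.

## Ensemble PCA

Members of a corresponded ensemble (≥3 structures) are superposed once
onto the designated reference — the inactive/apo state — and the 3N×3N
covariance of Cα coordinates about the ensemble **mean** is diagonalized
(economy SVD; at most M−1 non-null components for M structures).
Projections, by contrast, subtract the **reference** structure:
p_k = (X_aligned − X_ref)·PC_k. A structure's PC coordinates thus measure
deformation relative to a real conformation rather than a geometric
average; the reference projects to the origin while the centred cloud is
generally offset. Covariance about the reference instead of the mean is
available via a flag (variance fractions shift by a few percent between
conventions). Component signs are fixed deterministically
(largest-magnitude coefficient positive).

Derived measures: variance fractions λ_k/Σλ; transition coverage
Σ_{j≤k}(Δ·PC_j)²/|Δ|² for the aligned end-state difference Δ; Euclidean
PC1-2 distances between projected structures.

## Pathway scoring

* **Approach profiles**: per-frame rMSD (after superposition) and PC1-2
  distance to each intermediate; global minima and their frame indices are
  reported.
* **Asymmetry score** ∈ [0, 1]: the forward and reverse paths bound a loop
  in the PC1-2 plane. The frame is rotated so the start→target axis lies
  along x (anchored at the forward path's endpoints), both paths' PC2
  profiles are averaged in 20 bins along x, and the score is the ratio of
  the loop's semi-minor axis (half the largest binned forward−reverse gap)
  to its semi-major axis (half the pooled x extent). Coincident routes
  score 0; a loop as wide as it is long scores 1. A pooled-covariance
  ellipse was rejected because it cannot return 0 for coincident *curved*
  paths. The score is symmetric in its arguments and invariant to
  rotations of the PC plane; with binned means it is insensitive to frame
  density but not to gross outliers.
* **Projection histograms**: −k_B T ln of the normalized 2-D histogram of
  projections, empty bins masked, minimum shifted to zero — the standard
  free-energy-landscape-style view for overlaying sampled paths on
  densely sampled ensembles. It is a density transform only; the package
  never claims converged free energies.

## Synthetic fixtures

`make_hinge_models` builds a deterministic 59-residue two-domain toy: two
28-residue helical-lattice domains (2.0 Å rise, 100° twist, radius set for
3.8 Å consecutive Cα spacing) joined by a 3-residue extended linker, with
conformers produced by rotating the second domain rigidly about an axis
through the linker midpoint. Defaults: open = 30°, closed = 60°, giving a
5.6 Å end-state rMSD for the 30° rotation. Design rationale:

* the **extended linker** has low contact density, making the joint the
  softest spot of the network;
* the **pre-bent open state** splits the two otherwise degenerate bending
  directions of a straight rod — in-plane closure becomes the single
  softest mode (overlap ≈ 0.93 with the open→closed difference vector)
  and the hinge is stiff enough that its thermal oscillations stay
  protein-like. With a straight open state the lowest modes are global
  bends that overlap the transition at only ≈ 0.3 and the demon cannot
  ratchet the transition efficiently;
* the helix **rise of 2.0 Å** (slightly stretched relative to an ideal
  α-helix) sets the domain lever arm so the 30° rotation yields the
  intended ~5 Å class of conformational change.

The straight linker also has near-zero torsional stiffness, so the toy has
two near-zero non-rigid modes in addition to the six rigid-body modes;
rigid/zero modes are discarded by eigenvalue magnitude, not by fixed
count, precisely to tolerate such degeneracies.

What the toy does *not* emulate: tertiary contacts forming or breaking
across the interface during closure, anharmonic side-chain packing,
sequence heterogeneity, and solvent structure. Passing tests on the toy
demonstrate the correctness of the sampling and analysis machinery under a
clean single-hinge motion, not predictive accuracy for real proteins.

`make_pca_ensemble` draws Gaussian displacements with known standard
deviations along supplied orthonormal 3N directions, providing exact
ground truth for PCA recovery; in tests the directions are taken from
normal modes (orthogonal to rigid motions) and the amplitudes kept small
relative to the structure so the one-shot rigid superposition stays in its
linear regime.

## Numerical choices and degenerate inputs

* Kabsch superposition via SVD with proper-rotation (det = +1) correction;
  coincident/collinear point sets are flagged and fitted by translation
  only.
* Sequence identity across crystal forms is computed positionally over
  matched (chain, residue, insertion-code) keys — the ensembles this
  package targets are same-protein crystal forms, so no alignment
  algorithm is involved; the threshold defaults to 0.95.
* Residues with unresolved coordinates in any member are excluded by the
  correspondence step rather than modelled; variance fractions therefore
  refer to the common residue set.
* Alternate locations default to highest occupancy (ties → first listed);
  a strict policy that errors on duplicates is available.
* Problem sizes used in the shipped tests and in `scripts/acceptance.py`
  (59-residue toy, 3–5 seeds per direction, 10⁵-step thermostat runs,
  500-sample synthetic ensembles) were chosen as the smallest systems on
  which each property is statistically unambiguous.

## Known limitations

* The elastic network is built from the start structure only; contacts
  unique to the target do not shape the potential, which is also why
  forward and reverse routes can legitimately differ (the asymmetry score
  quantifies exactly this).
* The demon is a pure ratchet: it produces plausible low-energy corridors
  and visit orders, not kinetics or free-energy barriers.
* Default ENM constants stand in for an MD-calibrated parameterization;
  absolute eigenvalues and temperatures of crossing should not be
  over-interpreted.
* PDB handling is Cα-only by design: ligands, waters and side chains are
  ignored, and mmCIF input is out of scope.
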