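# Methods

This note documents the models, algorithms and design choices behind
`pomscout`: what each component computes, which knobs matter, what the
synthetic generators do and do not emulate, and where the desk-scale
stand-ins end and real physics would have to begin.

## The search problem

The package explores two families of potential-energy surfaces (PES):

* **Torsion spaces.** A flexible amino acid is reduced to its rotatable
  dihedrals; bond lengths and angles stay at their template values. Each
  dimension is an angle on [−180°, 180°), periodic.
* **Rigid-pose spaces.** A rigid molecule (or peptide fragment) is placed
  relative to the rigid cluster by its center-of-mass translation (x, y, z)
  and three intrinsic z-y-x Euler angles (h, i, j). Translations are bounded
  to a box circumscribing a shell 2–8 Å outside the cluster's terminal-
  oxygen hull; rotations are periodic. Poses that clash or drift beyond the
  interaction shell are legal points of the space — the sampler flags them
  and learns to avoid them (see *Invalid-point handling*).

Keeping fragments rigid means every relaxation in the pipeline operates in
search-space coordinates, not Cartesians: a "relaxed" pose is a local
minimum of the energy as a function of the 6 pose coordinates (or the n
torsions). This matches the study design in which the cluster and molecule
internal geometries are held fixed, and it makes capped and full
relaxations cheap and well-conditioned. Plain Cartesian relaxation is still
available for free molecules (`relax_geometry`).

## The rotatable-torsion rule

A bond is a torsion axis iff it is acyclic and both endpoints have degree
≥ 2, excluding three-fold methyl rotors (a pivot-end carbon bonded to
exactly three hydrogens). Amine and hydroxyl rotors count. On the shipped
ideal-geometry templates this yields 3 (Gly), 3 (Ala), 4 (Val), 5 (Leu),
5 (Ile), 6 (Met), 8 (Lys) dimensions. The isoleucine count is one lower
than a manual selection that includes a sixth chemically redundant
dihedral; the torsion list is therefore user-overridable when a specific
hand-picked set is required.

## Ideal α-Keggin geometry

The cluster [PMo₁₂O₄₀]³⁻ is built with exact T_d site symmetry from four
shells: P at the origin; four µ₄ oxygens on the T_d subset of body
diagonals at 1.53 Å; twelve Mo on cuboctahedron vertex directions at
3.55 Å; twenty-four bridging oxygens on the cuboctahedron edge-midpoint
directions at 3.55 Å; and twelve terminal oxygens radially outside each Mo
at Mo–O = 1.67 Å (the `scale` parameter). Perceived bonds then give every
Mo six oxygen neighbours (1 terminal + 4 bridging + 1 central) and every
terminal oxygen exactly one Mo.

Bond perception uses the summed-covalent-radius rule (cutoff
1.2 × (r_i + r_j), Cordero radii). Metal–metal contacts are excluded by
default: Mo–Mo distances in the cluster (≈3.55 Å) fall below the radius-sum
cutoff (3.70 Å) without being chemical bonds, and counting them would
corrupt coordination statistics. This is a chemistry decision, not a
numerical workaround.

The terminal-oxygen framework is the convex hull of those twelve atoms — a
cuboctahedron. Hull triangles whose dihedral is below 10⁻³ rad are merged,
yielding the 6 quadrilateral + 8 triangular faces; an outside point is
assigned to the face whose outward normal best aligns with the
centroid→point direction, with ties (within 10⁻⁹) reported as edge sites.

## The Gaussian-process surrogate

Inputs are normalized to the unit cube; energies are median-centered and
scaled by their interquartile range. The kernel is a product over
dimensions,

    k(x, x′) = σ_f² · Π_d k_d(Δ_d),
    k_d = exp(−Δ_d²/2ℓ_d²)                      (bounded dims)
    k_d = exp(−2 sin²(πΔ_d)/ℓ_d²)               (periodic dims, period 1)

with per-dimension lengthscales ℓ_d ∈ [0.03, 3] (normalized units) and a
fixed jitter of 10⁻⁶ (the backends are deterministic; the jitter is purely
numerical, escalated ×10 on Cholesky failure). Hyperparameters are set by
multi-start L-BFGS maximization of the log marginal likelihood. The signal
amplitude σ_f is bounded below by half the normalized data range: when most
samples sit on a flat background and a few in deep wells, the unconstrained
maximum-likelihood σ_f collapses, posterior uncertainty shrinks below the
well depth, and lower-confidence-bound exploration dies. The floor keeps
σ far from data on the scale of the observed energy range.

## Acquisition and the κ schedule

The next sample minimizes the exploratory lower confidence bound
a(x) = μ(x) − κₜ·σ(x), by multi-start L-BFGS from seeded quasi-random
starts plus the incumbent training minimum. The confidence coefficient
follows the GP-UCB growth schedule

    κₜ = sqrt(2·log(t^(d/2+2)·π²/(3δ))),   δ = 0.1,

(≈5–7 over typical runs). A constant κ of order 1–2 is offered as a
configuration option but is not the default: with a constant coefficient,
an already-sampled moderately deep well outbids the exploration value of
every unvisited region for the rest of the run, and the sampler never finds
a deeper competing basin. The growing schedule is the published default of
the structure-search code this pipeline follows.

Runs start from a scrambled-Sobol design of 5·dim points, refit
hyperparameters every 10 acquisitions (data are re-absorbed at fixed
hyperparameters in between), and are reproducible bit-for-bit from the run
seed: every stochastic element (design, acquisition starts, K-means,
t-SNE) derives its seed from it.

### Invalid-point handling

Geometries flagged by the validity check (steric clash at 0.6 × summed
covalent radii, or, for adsorption fixtures, a minimal inter-fragment
distance beyond the 8 Å interaction shell) are kept in the training set
with a clamped penalty energy of max(observed) + 1 eV, so the surrogate
learns a high plateau there without kernel-matrix corruption. Hard
calculator failures are clamped the same way; only failures (not validity
flags) count toward the 50% abort threshold, since in a box-bounded pose
space a large fraction of legal points is legitimately outside the shell.

## Minima mining and the refinement funnel

Candidate structures enter refinement by two complementary routes:

* **Surrogate minima mining**: multi-start minimization of the posterior
  mean from a quasi-random design plus all training points, deduplicated by
  periodic-aware distance (< 0.05 of the normalized range) and surrogate
  energy (< 10⁻³ eV).
* **Low-energy sampled points**: successfully evaluated configurations
  below a configurable energy percentile (default 50%), deduplicated the
  same way. This is the sampled-ensemble route used for contact-statistics
  analyses over many structures.

The funnel then applies, in order: (A) true single-point energies at the
candidate points; (B) clash removal; (C) relaxation capped at 100 steps
(L-BFGS-B, force tolerance 10⁻⁴ per coordinate); (D) an energy window of
0.2 eV above the post-relaxation minimum; (E) seeded K-means (k-means++) on
the one-dimensional relaxed energies, keeping the candidate nearest each
center — k defaults to 15 and k ≥ n degenerates to the identity; (F) full
relaxation of the representatives (cap 2000 steps); (G) duplicate merging:
pairs within 0.01 eV *and* 0.3 Å best-superposition RMSD (Kabsch; for
point-only candidates, 0.05 normalized periodic distance) collapse to the
lower-energy member. Every rejection is logged with its stage and reason;
attrition is monotone by construction, with stage F count-preserving.

Energy-profile K-means (rather than structure-space clustering) is
deliberate: the stage exists to pick representative energy levels, and
clustering in structure space would impose a geometry metric the method
does not otherwise use.

## The empirical stand-in potential

Purpose: make the full pipeline executable and testable on a desk. It is
**not** fitted to reproduce any first-principles numbers; binding-energy
magnitudes it produces (≈ −0.3 … −1 eV for the shipped systems) carry no
quantitative meaning beyond the pipeline's own consistency.

Terms, all pair distances in Å, energies in eV:

* **Lennard-Jones** 4ε[(σ/r)¹² − (σ/r)⁶] with per-element ε, σ
  (Lorentz–Berthelot combination) for all inter-fragment pairs and
  intra-fragment pairs ≥ 3 bonds apart (1–4 pairs scaled by 0.5; closer
  pairs are rigid internal geometry).
* **Screened Coulomb** q_iq_j·14.3996/(ε_r·r) with ε_r = 4 and heuristic
  partial charges: tag-dependent values on the cluster (terminal O −0.50,
  bridging O −0.35, central O −0.60, Mo +0.85, P +1.20), element-based
  values on molecules, polar H +0.35; the residual is spread uniformly so
  each fragment carries exactly its formal charge (−3 e for the cluster).
* **Hydrogen-bond wells**: donor-H (H on N/O/S) to acceptor (N/O/S) pairs
  get a 10-12 potential D[5(σ_hb/r)¹² − 6(σ_hb/r)¹⁰] with D = 0.25 eV,
  σ_hb = 1.90 Å instead of LJ. This pulls donor hydrogens to ≈1.9 Å from
  framework oxygens — inside the 2.2 Å contact-count cutoff — so
  contact-rich poses are genuinely lower in energy, which is the physical
  mechanism behind the MDC–energy anticorrelation the analytics measure.
* **Torsion barriers** ½k(1 + cos 3θ) per rotatable torsion, k = 0.02 eV.

The potential is additive over non-interacting fragments, invariant under
joint rigid motions, and rejects geometries with atoms closer than 0.05 Å.
Gradients are central finite differences (step 10⁻⁴) in whatever
coordinates are being relaxed. Distance-independent pair coefficients are
cached per topology, so pose scans cost one distance matrix per evaluation.

## Planted landscapes

The analytic test surfaces are sums of negative Gaussian wells,
Σᵢ −dᵢ·exp(−‖q−cᵢ‖²/2wᵢ²) (periodic-aware displacement on periodic
dimensions), plus an optional seeded band-limited cosine roughness term that
respects periodicity. The deepest well is unique by construction, so the
global minimum is known exactly — the ground truth for recovery tests.

Default well widths scale with dimension so that the 2σ basin of a well
occupies ≈7% of the domain volume regardless of dimensionality. A
dimension-independent absolute width would shrink that fraction
exponentially with d, producing landscapes in which no sampler — grid,
random, or surrogate-driven — can locate a basin at realistic budgets; the
PES of the systems this package emulates instead show a few broad competing
basins covering a substantial part of the accessible space, which is what
the default reproduces. Widths, depths (0.4–1.0 eV), domain and
periodicity are all overridable, and centers are redrawn until all pairwise
separations reach 3× the largest width.

## Synthetic molecular inputs

Residue templates are realized from ideal internal coordinates (C–C 1.53,
C–N 1.47, C=O 1.22, C–O(H) 1.36, C–S 1.81, C–H 1.09, N–H 1.01, O–H 0.97 Å;
tetrahedral and sp² angles) via natural-extension-reference-frame placement
of a named Z-matrix. Template bond graphs equal the perceived ones, and
side-chain rotamers (χ₁ gauche(−), deeper dihedrals anti/staggered) were
chosen by a design-time strain scan to be clash-free both as monomers and
inside chains.

Peptide fragments are rigid extended strands with trans peptide bonds.
The backbone uses φ = −90°, ψ = 170° (polyproline-II-like) rather than the
textbook flat zigzag (φ = ψ = 180°): in a perfectly flat chain, branched
side chains collide with the neighbouring carbonyl oxygens at < 1.5 Å, so
the flat conformation is not realizable for the residue set shipped here.
Side-chain hydrogens on carbon in alkyl-bearing residues
(Ala/Val/Leu/Ile/Lys) are tagged `sidechain-alkyl-H` for contact analyses.

What the generators do *not* emulate: conformational disorder of the
peptide (the chain is one fixed strand), solvent and ionic strength,
polarization or charge transfer, cluster distortion on binding, and any
quantum-chemical observable (orbital gaps and population charges are
pass-through report fields, never computed). Passing tests therefore
demonstrate the machinery — sampling efficiency, funnel exactness, contact
statistics — on systems with those simplifications, not the energetics of
the real complexes.

## Numerical choices and degenerate inputs

* Relaxations and acquisition/mining searches use L-BFGS-B; inaccessible
  geometries probed by a line search return a large finite penalty so the
  search backtracks instead of crashing.
* Kernel-matrix jitter starts at 10⁻⁶ and escalates ×10 up to 8 times
  before failing.
* Coplanarity tolerance for face merging is 10⁻³ rad (configurable), ample
  for the exact build and tolerant of mildly distorted clusters.
* Tie-breaks: minimal-distance pairs report the lowest-index pair;
  site-classification ties within 10⁻⁹ are "edge"; K-means representative
  ties resolve to the first nearest candidate.
* Degenerate analytics inputs (all-identical contact counts) report NaN
  with an "undefined" sign rather than a spurious correlation.
* t-SNE uses PCA initialization and the run seed, making embeddings
  deterministic; the perplexity is capped by (n−1)/3 with a clear error
  suggesting a smaller value.

## Problem sizes

The shipped study configurations are desk-scale by design: search budgets
of 20·dim evaluations for landscape benchmarks, 100–200 evaluations for
adsorption runs, 64–160 mining starts, and peptide fragments of 2–8
residues. These sizes were chosen so that each seeded study completes in
minutes on one core while still exercising every stage of the pipeline;
all of them are configuration values, and larger studies only require
larger budgets.

## Known limitations

* The stand-in potential has no polarization, anisotropic metal chemistry,
  or fitted parameters; only signs, orderings and pipeline behaviour are
  meaningful.
* Rigid fragments exclude induced-fit effects; the funnel's "full
  relaxation" is full only within the search-space coordinates.
* The rotatable-bond rule is topology-only; it cannot reproduce manual
  dihedral selections that split chemically equivalent rotors.
* LCB acquisition over large bounded boxes over-explores the boundary;
  the adsorption fixture mitigates this with the interaction-shell
  validity check rather than a reparameterization.
* The GP scales as O(n³) in evaluations; budgets beyond ~10³ points would
  need sparse approximations that are out of scope here.
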