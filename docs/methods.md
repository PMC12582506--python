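# Methods

## Strain from conformation pairs

For atom *i* with neighbours *j*, the deformation gradient **F**ᵢ minimises
Σⱼ wⱼ‖Δx_ij − **F**ᵢ ΔX_ij‖², where ΔX and Δx are neighbour displacement
vectors in the reference and deformed conformations. The solution is the
closed-form normal equation **F** = (Σ w Δx ΔXᵀ)(Σ w ΔX ΔXᵀ)⁻¹. No
structural superposition is performed at any point: the Lagrangian strain
**E** = ½(**F**ᵀ**F** − **I**) cancels any rigid factor of **F** exactly, so
results are independent of how the models happen to be framed. Principal
strains are the eigenvalues of **E** in ascending order (ε₁ compression-most,
ε₃ extension-most).

Neighbourhoods default to a 9 Å radius over backbone atoms (N, CA, C, O)
with the **intersect-all** rule: atom *j* counts as a neighbour of *i* only
if it is within the radius in *every* conformation of the ensemble, so all
pairwise comparisons are computed on identical supports and differences
between pairs reflect deformation, not neighbour churn. A per-pair mode
(radius test in the reference only) is available; both radius and mode are
parameters since results should always be checked for robustness against
them. Rank-deficient neighbourhoods (fewer than 4 neighbours, or collinear/
coplanar geometry) are an error, never silently regularised — a
pseudo-inverse would fabricate strain where the data cannot determine it.

Ensembles are built by intersecting atom identities
(chain, residue number, insertion code, atom name) across conformations,
after first excluding any residue not modelled in all of them. Alternate
locations other than blank/'A' are dropped with a warning; hydrogens are
excluded by default (cryo-EM models generally lack them); residues are never
renumbered.

## Elastic pseudoenergy

The Saint Venant–Kirchhoff density Ψ(**E**) = (λ/2) tr(**E**)² + μ tr(**E**²)
is non-negative for admissible constants (μ > 0, λ ≥ −2μ/3) and zero only at
zero strain. Per-atom energies are Ψ(**E**ᵢ)·vᵢ·φ with vᵢ the Bondi van der
Waals sphere volume and φ = V/Σⱼvⱼ the whole-molecule volume over the summed
volume of analysed atoms. φ restores extensivity when only a subset of atoms
(Cα, backbone) is analysed; on uniform-deformation fixtures the total is
stable to subset choice within a few percent, which is φ's purpose and the
limit of what it can do for spatially heterogeneous deformations.

Default constants are a Young modulus of 1 GPa and Poisson ratio 0.3
(λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν))), converted to k_BT/Å³ at 298 K. The
measured range for protein stiffness spans roughly 0.1–10 GPa, so **reported
magnitudes are calibration-sensitive and scale linearly with the modulus**;
relative comparisons across conformations and residues are the robust
output. Per-residue energies are sums over the residue's analysed atoms
(energy is extensive); the mean per atom is available as an alternative.
Cycle landscapes compare each conformation to its position cognate in a
reference assembly (F1, F2, … against F0) and report the per-subunit total.

The word *pseudoenergy* is deliberate: the protein is modelled as a
homogeneous, isotropic, unstressed elastic medium, all of which is false in
detail (anisotropy, heterogeneity, pre-stress, plastic rearrangement are all
ignored). The quantity is a principled deformation measure on an energy
scale, suitable for ranking and localisation, not a thermodynamic free
energy.

## Cycle ordering

The (a, b) entry of the dissimilarity matrix is the mean over shared atoms
of ε₃ for deformed = a against reference = b (⟨−ε₁⟩ and total pseudoenergy
are selectable alternatives; on well-behaved ensembles they give the same
ordering). The matrix is mildly asymmetric because strain is defined against
a reference; it is symmetrised by arithmetic mean before embedding. Metric
(SMACOF) MDS with random initialisation is run many times (default 100);
each solution is centred and aligned to the first by orthogonal Procrustes
(rotation and reflection) before averaging, since raw stress minima are
arbitrary up to rigid motions and averaging unaligned solutions would be
meaningless. The cyclic order is the polar-angle order about the embedding
centroid, with lexicographic tie-breaks; agreement with a known order is the
maximum Spearman correlation over all rotations and both orientations of the
cycle (1.0 means identical up to the symmetries a cycle actually has).

## Mechanically active regions

Per-residue energy trajectories across the ordered cycle are summarised by
their variance; residues at or above the 0.90 variance quantile are selected
(ties included). Selected trajectories are correlated pairwise (Pearson) and
the rows of the correlation matrix are clustered hierarchically on Euclidean
distances, average linkage, cut at `n_regions` clusters (default 4 — a
parameter, not a biological constant; inspect the dendrogram before trusting
any particular cut). Constant trajectories have undefined correlations and
are dropped with a warning. Group comparisons use the Kruskal–Wallis omnibus
test and pairwise two-sided Mann–Whitney U with Bonferroni correction over
the number of pairs.

## Polar contacts and interface energies

A polar contact is an N/O (optionally S) heavy-atom pair from different
residues within 3.9 Å; pairs within 3.5 Å are graded optimal, the remainder
suboptimal. The criterion is distance-only: the models carry no hydrogens,
so no angular or donor/acceptor term is defensible. Intra-residue pairs and
the covalent peptide-bond N(i+1)–O(i) pair are excluded. Partners are
classified per home chain: same chain cis; adjacent motor subunits
trans-forward/trans-backward by declared ring orientation; other chains by
their molecule class (substrate, nucleotide, partner protein). A residue's
pseudoenergy is split across interfaces in proportion to its contact counts,
so a residue's contributions always sum to its full energy.

## Kinetic model

M subunits occupy states 0…N−1 (internally 0-based; the reaction coordinate
θ = 2πs/N enters only through differences, so the choice of origin is
immaterial) on a periodic landscape ΔE_el(θ) in k_BT. Adjacent subunits
couple through E_c = (K/M)(1 − cos(θ_{m+1} − θ_m − δ)); δ = π/3 by default,
which makes evenly staggered hexamer configurations coupling-free. Rates are
k_ab = τ⁻¹ Γ_ab with Γ_ab = (1 + e^{(E(b)−E(a))/k_BT})⁻¹, one subunit moving
one step at a time, and driven edges multiply by e^{±Δμ/2k_BT} so that the
rate *ratio* carries exactly e^{Δμ/k_BT} — local detailed balance holds to
machine precision by construction (the sigmoid form is one of many rate
choices satisfying it). Γ is evaluated in an overflow-safe form, so
arbitrarily large energy differences degrade gracefully to absorbing states
rather than overflowing.

Working units are k_BT = 1 and τ = 1; per-edge τ values can be supplied to
calibrate absolute time against experiment, which is external data. Default
driven edges place one driven transition at the end of each of the six
position blocks (the natural site of nucleotide exchange in a hand-over-hand
scheme); any edge set can be configured, and reproducing a specific system
requires its actual set. The Gillespie implementation recomputes only the
moved subunit's and its neighbours' rates per event and never enumerates the
N^M state space; exact Boltzmann enumeration is provided only for small
models (used in the equilibrium test at M = 2, N = 6). Winding (one
translocation step per completed cycle) is counted at the N→1 wrap.

The shuffle experiment compares translocation speed distributions under the
native landscape ("ordered"), random permutations of all N values
("fully-shuffled"), and permutations of the within-position assembly order
with fixed position order ("partially-shuffled", 5! = 120 permutations for
N = 30, six positions). The coupling analysis reports dwell-time-weighted
mean backward/forward coupling energies and the coupling force
(K/M)[sin(θ_{m+1}−θ_m−δ) − sin(θ_m−θ_{m−1}−δ)] per visited conformation;
unvisited conformations are reported missing, not zero.

## Synthetic fixtures and what they establish

Fixture clouds are uniform balls at 0.05 atoms/Å³ (near protein heavy-atom
packing) labelled as poly-alanine backbones, so residue-level aggregation
and file round-trips are exercised. Affine fixtures carry exact ground-truth
strain ((AᵀA − I)/2 for linear part A); planted cycles apply a uniaxial
stretch whose axis rotates by π j/n around the cycle (a stretch axis has
period π, closing the schedule), making relative strain monotone in cyclic
label distance; toy landscapes are raised cosines with an exact max − min.
Defaults for the recovery studies: amplitude 0.1 (a 10% stretch, the scale
of large inter-conformation deformations), coordinate noise 0.02 Å
(amplitude/5), 30-conformation cycles, 100 MDS realisations.

Passing on these fixtures establishes the estimator's correctness (exact
affine recovery, rigid-motion nulls, monotone dissimilarities) and the
pipeline's statistical behaviour at realistic signal-to-noise. It does not
establish that real cryo-EM ensembles satisfy the assumptions: real models
carry position-dependent coordinate error, missing density, and
non-affine local deformation, and the elastic constants are not known
per-protein. Problem sizes in the test suite and acceptance script
(60–200-atom clouds, 20 master seeds, 10⁶ Gillespie events, 20 ordered vs
100 shuffled runs of 2×10⁴ events) were chosen as the smallest at which the
statistical checks are stable.

## Numerical choices

- Strain-tensor symmetry is enforced to 1e-10; rotation nulls hold to 1e-9;
  neighbour covariances with relative eigenvalue below 1e-9 are errors.
- Normal equations are solved by batched 3×3 `solve`; weighted and
  unweighted paths coincide for equal weights.
- MDS realisation seeds derive from one master seed (`SeedSequence`); the
  Gillespie RNG is a seeded PCG64, so trajectories are bit-reproducible.
- Ties (variance threshold, cluster order, polar-angle order) break
  lexicographically by residue/label key.
- Degenerate inputs fail loudly: empty ensembles, all-coincident embeddings,
  zero total rates (absorbing states are flagged on the trajectory),
  incompressible Poisson ratio.
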