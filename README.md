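# elastocycle

Residue-scale elastic analysis of protein conformational ensembles, and a
driven kinetic model of ring assemblies constrained by the inferred energy
landscape.

Many molecular machines — hexameric AAA+ ATPases such as RuvB are the
motivating case — work by cycling each subunit through a closed series of
conformations while translocating a substrate. Given two or more atomic
models of the same molecule (cryo-EM, crystallography, or predicted),
`elastocycle` answers four questions:

1. **How deformed is each part of the structure between two conformations?**
   For every atom *i*, the deformation gradient **F**ᵢ is the linear map that
   best relates local displacement vectors to the atom's neighbours between
   the two models (weighted least squares, no superposition needed). The
   Lagrangian strain **E**ᵢ = ½(**F**ᵢᵀ**F**ᵢ − **I**) is exactly zero for
   rigid motion; its eigenvalues ε₁ ≤ ε₂ ≤ ε₃ are the local principal
   strains.
2. **How much elastic pseudoenergy does a deformation store?** Treating the
   protein as a homogeneous isotropic Saint Venant–Kirchhoff material,
   Ψ(**E**) = (λ/2) tr(**E**)² + μ tr(**E**²) ≥ 0, and the per-atom energy is
   ΔE_el,ᵢ = Ψ(**E**ᵢ) vᵢ φ with vᵢ the atom's van der Waals volume and
   φ = V / Σⱼvⱼ a whole-molecule extensivity correction for the analysed
   atom subset. Energies are reported in k_BT. This is a *pseudo*energy — a
   deformation proxy, not a free energy.
3. **In what order do the conformations occur?** All pairs are compared by
   mean strain (⟨ε₃⟩ by default), the resulting dissimilarity matrix is
   embedded in 2-D by metric MDS (many realisations, Procrustes-aligned and
   averaged), and a cyclic order is read off the embedding. Per-residue
   energy trajectories across the cycle then localise mechanically active
   regions (top-decile variance, correlation clustering), and polar-contact
   analysis attributes residue energies to interfaces (substrate,
   nucleotide, neighbouring subunits) by contact fractions.
4. **Is the inferred landscape consistent with processive motion?** A ring
   of M subunits on the N-state periodic landscape, with Kuramoto coupling
   E_c = (K/M)(1 − cos(Δθ − δ)) and a chemical drive Δμ on designated
   transitions, is simulated exactly by the Gillespie algorithm under local
   detailed balance, k_ab = τ⁻¹(1 + e^{ΔE/k_BT})⁻¹ (times e^{±Δμ/2k_BT} on
   driven edges). Landscape-shuffling and coupling-force analyses probe how
   the ordering of states shapes translocation.

## Worked example

```python
import numpy as np
import elastocycle as ec
from elastocycle.kinetics import default_driven_edges

# strain + pseudoenergy of a known uniform 10% dilation
fx = ec.make_affine_ensemble(100, [1.1 * np.eye(3)], seed=7)
nb = ec.build_neighborhoods(fx.ensemble, radius=9.0)
field = ec.strain_field(fx.ensemble, "def0", "ref", nb)
print(f"mean eps3 = {field.mean_eps3:.6f}")

pf = ec.pseudoenergy_field(fx.ensemble, "def0", "ref", nb,
                           ec.ElasticParameters(lam=1.0, mu=1.0))
print(f"total pseudoenergy = {pf.total:.2f} kBT (phi = {pf.phi:.2f})")

# recover the order of a planted 12-conformation cycle
cyc = ec.make_cycle_ensemble(n=12, amplitude=0.1, noise_sigma=0.02,
                             n_atoms=80, seed=7)
D = ec.dissimilarity_matrix(cyc.ensemble, metric="mean-eps3")
emb = ec.mds_embed(D, n_realisations=100, seed=7)
order = ec.cyclic_order(emb)
print("recovered order:", " ".join(order))
print(f"circular agreement = {ec.circular_agreement(order, cyc.order):.2f}")

# drive a hexamer over a 6 kBT barrier
model = ec.KineticModel(landscape=tuple(ec.make_toy_landscape(30, 6.0)),
                        M=6, K=6.0, delta_mu=8.0,
                        driven_edges=default_driven_edges(30))
traj = ec.gillespie(model, [0, 5, 10, 15, 20, 25], n_events=50_000, seed=7)
print(f"translocation speed = {ec.translocation_speed(traj):.5f} cycles/tau")
```

Output:

```
mean eps3 = 0.105000
total pseudoenergy = 147.74 kBT (phi = 1.00)
recovered order: c06 c07 c08 c09 c10 c11 c00 c01 c02 c03 c04 c05
circular agreement = 1.00
translocation speed = 0.00572 cycles/tau
```

The dilation's strain is the closed form ½(1.1² − 1) = 0.105 at every atom.
The recovered order is the planted cycle up to rotation (cyclic orders have
no distinguished start), hence agreement 1.0. The driven hexamer advances
processively: about one full cycle per 175 τ per subunit.

A CLI mirrors the library: `elastocycle ingest / strain / energy / order /
simulate / synth` (see `elastocycle --help`). Real structures are ingested
from local PDB/mmCIF files; conformations labelled `<Position><k>` (e.g. F1,
F2 against a reference F0) get their reference cognates mapped
automatically.

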