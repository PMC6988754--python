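# Methods

## Model overview

`lh2exciton` models the Q_y excitations of an LH2-like pigment aggregate
as a Frenkel exciton system extended with inter-pigment charge-transfer
(CT) states. The Hamiltonian (all entries in cm⁻¹) has a locally-excited
(LE) block — site energies ε_i on the diagonal, electronic couplings V_ij
off-diagonal — a diagonal CT block, and an LE–CT coupling block; CT–CT
couplings are fixed at zero, matching the block structure the model is
defined with. CT basis functions carry no transition dipole, so CT states
borrow intensity only through mixing.

The basis order is fixed everywhere: 2n B850 sites unit-major (α before
β), then n B800 sites, then CT states. All writers, readers and the
symmetry machinery rely on this order.

## Synthetic ring generator

The generator emulates the study conditions of the three complexes
(high-light HL, low-light LL, PucD) without requiring any structure
download:

* **Topology.** n_units = 9 αβ units; 18-site alternating inner ring plus
  a 9-site outer ring, exact C9 symmetry about z.
* **Geometry defaults.** B850 radius 26 Å, B800 radius 31 Å displaced
  −16 Å along the ring axis; transition dipoles 6.3 D (typical BChl a
  Q_y), in-plane, near-tangential with alternating ±10° offsets for α/β.
  These values give head-to-tail nearest-neighbor point-dipole couplings
  of a few hundred cm⁻¹ (−543/−511 cm⁻¹ intra/inter at the defaults),
  the right order of magnitude for the B850 ring, and make both the
  k = ±1 and k = ±8 pairs carry dipole strength (the ±8 brightness comes
  from the alternating offset; pure tangential dipoles would leave only
  ±1 allowed). All geometry parameters are configurable.
* **Site energies.** Per-complex means and per-frame Gaussian standard
  deviations for the three site classes (αBChl, βBChl, B800) are packaged
  in `parameters.COMPLEX_PARAMS`; disorder draws are independent per site and
  frame.
* **Orientational/positional jitter.** Static geometric disorder is an
  azimuthal rigid jitter: each pigment's center *and* dipole are rotated
  about the ring axis by a Gaussian angle (default SD 3°, i.e. ~1.4 Å of
  arc at the B850 radius), plus an independent radial displacement
  (default SD 0.3 Å). The jitter angles of the two pigments of an
  intra-chain pair correlate with `corr_intra` and those of an
  inter-chain pair with `corr_inter`. A perfectly correlated pair
  co-rotates rigidly, which leaves its distance and orientation factor κ
  exactly invariant — the mechanism by which an H-bond tethering a βBChl
  to the neighbouring unit narrows the κ distribution of the inter-chain
  pairs. A dipole-only rotation model was rejected: for near-collinear
  head-to-tail pairs κ depends on it only at second order and the common
  mode then *widens* the κ distribution, the opposite of the tethering
  effect.
* **Correlation feasibility.** The target correlation matrix (alternating
  intra/inter correlations on a ring, zeros elsewhere) is positive
  semidefinite only for ρ_intra + ρ_inter ≤ 1 (plus boundary cases);
  infeasible settings are projected by clipping negative eigenvalues to
  zero before sampling. The (1, 1) corner lands on a smoothly decaying
  ring correlation with neighbor ρ ≈ 0.7.
* **Randomness.** One `numpy.random.Generator` per ensemble, seeded once.
  Draw order per frame: site energies (site-major), B850 jitter angles,
  B800 jitter angles, radial displacements. Fixtures are therefore
  bit-reproducible for a fixed seed.
* **CT manifold.** Two CT states per adjacent αβ pair of the 18-ring
  (both transfer directions; 36 for the nonamer). Energies are Gaussian
  around a configurable mean and always include the −1008 cm⁻¹ alignment
  shift; the default mean places them 2000 cm⁻¹ above the highest LE
  energy, consistent with CT states lying above the Q_y excitations.
  Each CT state couples to its donor and acceptor LE with a default
  250 cm⁻¹ (configurable per entry); the B800 ring has no CT states.

What the generator does **not** emulate: protein/lipid atoms,
carotenoids, out-of-plane (doming) distortions, correlated site-energy
fluctuations, non-Gaussian disorder, or any force-field energetics.
Passing tests on these ensembles therefore validate the pipeline's
machinery and its directional responses, not force-field realism.

## Geometry descriptors

Macrocycle centers are the arithmetic mean of the four macrocycle N
atoms. The Q_y dipole axis is the unit vector from N_B to N_D (the
standard BChl a convention); both the atom quadruple and the residue-name
mapping are configuration (`SelectionRules`), since different PDB entries
name the pigments differently and the acetyl-dihedral atom quadruple is
not standardized. κ follows the Förster definition
κ = μ̂₁·μ̂₂ − 3(μ̂₁·r̂)(μ̂₂·r̂) ∈ [−2, 2]. Torsions are signed IUPAC angles
(cis = 0°, trans = 180°, range (−180°, 180°]). H-bond lengths are
heavy-atom distances (acetyl O to Tyr OH / Trp NE1), since MD-derived
PDB snapshots may lack hydrogens. Pair classes follow the unit indices:
(α_u, β_u) is intra-chain, (β_u, α_{u+1 mod 9}) inter-chain, everything
else (including B800 contacts) "other".

## Couplings

* **Point-dipole:** V = C κ μ_i μ_j / r³ with C = e²/(4πε₀) expressed in
  cm⁻¹·Å³·D⁻² (5034.1, derived from CODATA constants at import).
* **Transition charges:** Coulomb sums over point charges standing in for
  the transition densities. Synthetic pigments use a ±q pair along the
  dipole axis reproducing |μ| (separation 1 Å by default); charge tables
  for real structures are user-supplied, as deriving them requires
  excited-state quantum chemistry that is out of scope.
* **Environment term:** isotropic polarizable sites acquire induced
  dipoles μ_k = α_k E_tot(r_k) self-consistently (Jacobi iteration with
  over-relaxation ω = 0.7, convergence 1e-8 D on the maximum dipole
  change, cap 500 iterations; a direct dense solve of (I − αT)μ = αE₀ is
  provided as the oracle and for small systems). The coupling correction
  is v_env = −Σ_k μ_ind,k(ρ_j)·E_i(r_k). The overall sign of this term is
  a convention (fixed here so that polarizable matter between two
  parallel transition dipoles screens their coupling); only its
  reciprocity under i↔j exchange is a guaranteed property, and the tests
  check exactly that plus the screening sign on a fixed slab fixture.
  A Thole-style exponential damping of the dipole–dipole tensor is
  available but off by default; close, strongly polarizable site pairs
  can hit the polarization catastrophe, and the solver then fails loudly
  with its last residual rather than returning a diverged answer.

## Exciton analysis

* **Symmetry averaging.** The Hamiltonian is averaged over frames, then
  every matrix element is replaced by the mean over its orbit under the
  C9 rotation (which permutes LE sites and CT labels simultaneously).
  Orbit members receive the identical float, so the result commutes
  exactly with the ring permutation. Exciton widths under disorder are
  defined on this averaged Hamiltonian; per-frame widths can be computed
  but are non-canonical.
* **k assignment.** Each eigenstate is labelled by the 18-site Fourier
  mode with maximal paired power P_k + P_{−k}; degenerate partners get
  +k and −k, and states with maximal paired power below 0.5 (strong
  disorder, CT-dominated) are flagged undefined. The exciton width is the
  mean energy of the ±8 pair minus the mean of the ±1 pair (pair means
  are used; in the symmetric ring the members are degenerate so the
  choice only matters under disorder).
* **Coupling-sign gauge.** Published coupling tables for these rings
  quote positive values, while the bright red-most pair is conventionally
  k = ±1, which requires the band minimum at small |k|. Since flipping
  the sign of every β basis function negates both nearest-neighbor
  couplings without changing any observable except the k labels, the
  builders that start from tabulated magnitudes
  (`nearest_neighbor_ring_hamiltonian`, `tabulated_hamiltonian`) apply the
  physical negative (head-to-tail) gauge by default. With it, the
  NN-only widths come out 1061/815/785 cm⁻¹ for HL/LL/PucD — within 10%
  of the full-coupling values (1098/856/842), the remainder coming from
  beyond-nearest-neighbor couplings not included in the NN model.
* **CT shifts.** Exact shifts are obtained by matching eigenstates of the
  CT-free and full Hamiltonians by maximal LE-block overlap (squared
  overlap < 0.5 flags ambiguity); the second-order estimate
  Σ_m |W_sm|²/(E_s − ε_m) is returned alongside and agrees within 5% when
  the gap exceeds ~10× the coupling.
* **Degeneracy/brightness tolerances.** Degenerate pairs are counted at
  1e-4 cm⁻¹; a state is bright if its dipole strength exceeds 1e-6 of the
  maximum. Both are configurable.

## Spectra

Lineshapes are sums of area-normalized Lorentzians weighted by dipole
strength, with band-resolved HWHMs (per-complex low-band 150/280/280 cm⁻¹
for HL/LL/PucD, high band 180 cm⁻¹) and a rigid −1247 cm⁻¹ global shift.
States are assigned to the low/high band by an energy cutoff placed
midway between the mean B850 and mean B800 diagonal energies (the split
is configurable; no character-based assignment is attempted). The default
grid is 9000–15000 cm⁻¹ at 1 cm⁻¹. Because Lorentzian tails are fat, the
integral over a grid spanning ±10 HWHM captures only ~94% of the total
dipole strength; the 1% normalization property holds on wide grids, and
a `narrow_grid` flag marks spectra whose grid clips any state's ±10 HWHM
neighbourhood. No vibronic or asymmetric lineshapes are attempted.

The V2-scaling experiment reports both raw and globally shifted peak
positions, leaving the mapping onto any particular experimental reference
band to the caller.

## Statistics

The bond-length regression is plain OLS (statsmodels), failing loudly on
exactly collinear designs; which bond lengths enter is configuration, not
hard-coded. Class statistics use the n−1 SD and Student-t 95% confidence
intervals. The per-residue contribution ledger is a first-order classical
estimate (difference charges × residue charges, optional −½αE² induced
term): it is additive over residues by construction and reproduces signs
and distance trends of environment switch-off analyses, not their quantum
magnitudes.

## Problem sizes

Default analyses use 9 units (27 pigments), 50-frame ensembles for
averaging/recovery studies, 10-frame ensembles for the dimer-sampling
layout (9 symmetry copies × 10 frames = 90 geometries per class), and
≤ 30 polarizable sites in the solver cross-checks; these sizes make every
statistical check well-conditioned while keeping the full suite and the
acceptance script fast.

## Known limitations

* The environment screening uses isotropic polarizabilities and point
  transition charges; no anisotropy, no ab initio transition densities.
* CT parameters are synthetic stand-ins (configurable), not diabatization
  outputs; only their structural role in the Hamiltonian is modelled.
* The disorder model is static and frame-wise independent; no dynamic
  (homogeneous) broadening beyond the Lorentzian convolution.
* B800–B850 and beyond-nearest-neighbor couplings are included only when
  computed from geometry (`couple_frame` without a cutoff), not in the
  tabulated NN builders.
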