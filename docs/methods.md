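# Methods

This note records the model, the numerical choices, and the verification
strategy of `corehole2`, in enough detail that a maintainer can judge what
the tests demonstrate — and what they do not.

## Model and working equations

The package computes vertical core-level ionization energies of closed-shell
molecules from a canonical Hartree–Fock or Kohn–Sham reference, at two
second-order levels under the core-valence separation (CVS).

**Configuration space.** The (n−1)-electron space is restricted to
configurations with exactly one active-core hole: the one-hole (1h) states
`Φ_I` and the two-hole-one-particle (2h1p) states `Φ_{Ij}^a` with one
active-core hole `I`, one inactive-occupied hole `j`, and one particle `a`.
Couplings between core-hole and pure valence-hole configurations are
dropped a priori (integral-based CVS), which is implemented *structurally*:
the only density-fitting blocks ever materialized are core-core (`J_CC`),
core-inactive (`J_CO`), core-virtual (`J_CV`) and inactive-virtual
(`J_OV`), so a discarded coupling cannot even be assembled. Under CVS with
a frozen chemical core the ground-state MP2 doubles amplitudes drop out of
the ionization correction entirely; the terms that would carry them are
therefore absent by construction, not merely neglected.

**Density fitting.** Four-center integrals are factorized
`(pq|rs) = Σ_P J_pq^P J_rs^P` with `J = I V^{-1/2}` built from three-center
(`I`) and two-center (`V`) Coulomb integrals over an auxiliary basis. The
metric inverse square root uses a symmetric eigendecomposition with an
eigenvalue drop threshold (default `1e-10`) as the conditioning guard for
near-linearly-dependent auxiliary sets. The fit is exact when the auxiliary
set spans the pair space, which the test suite exploits as an oracle (see
below). No block with two virtual indices exists, so peak storage is
`O(n_aux · n_occ · max(n_occ, n_virt))`.

**Perturbative level (CIS(D)-type).** The second-order correction to the
Koopmans energy `−ε_K` contracts two coupling classes
`V_{I,ja}^K = −Σ_Q J_IK^Q J_ja^Q` and `V_{Ia,j}^K = −Σ_Q J_Ia^Q J_jK^Q`
with doubles coefficients `c = V / (ε_I + ε_j − ε_a + ω)` evaluated once at
`ω = −ε_K`, in the combination `Σ V (2c − c′)` (direct minus
exchange-permuted). Fixing the frequency at the Koopmans value — never
iterating it — is precisely what distinguishes this method from ADC(2).
It coincides with the diagonal, frequency-independent second-order
self-energy (ΔMP2).

**Iterative level (ADC(2)-type).** The same contraction defines an
ω-dependent folded Jacobian over the active-core singles space; its
eigenvalue must equal the fold-in energy. Because CVS shrinks the singles
space to a handful of orbitals, the solver builds the `N_act × N_act`
effective matrix explicitly (one σ-application per unit vector) and
diagonalizes it densely inside a fixed-point loop on ω — mathematically
identical to the subspace-iteration treatment a general-purpose code would
use, but exactly reproducible, and the σ build (the cost-dominant step,
`O(N_act N_inact N_virt N_aux)`) is unchanged.

**Spin adaptation and scaling.** All contractions are spin-adapted
closed-shell spatial-orbital expressions. The opposite-spin / same-spin
split is `OS = Σ V·c`, `SS = Σ V·(c − c′)`, the unique decomposition
consistent with the MP2 direct/exchange separation; `(1,1)` recovers the
plain method bit-exactly and `(0,0)` reduces both methods to `ω = −ε`
exactly. SOS uses `(1.3, 0)`. Double-hybrid tags scale the second-order
terms by the functional's correlation-mixing coefficients, read from
`src/corehole2/data/dh_registry.yaml` — a user-editable registry with
per-entry provenance, because these coefficients belong to the functional
definitions, not to this code. The registry ships B2PLYP (0.27/0.27),
PBE0-2 (0.5/0.5) and an SOS0-PBE0-2 entry whose opposite-spin coefficient
(0.65) follows the SOS0 convention (base mixing × 1.3); the citation field
of each entry says where its numbers come from, and the entry should be
adjusted if a different primary-source value is preferred. For a KS
reference no exchange-correlation quantity is evaluated after the SCF:
the solvers consume only orbital energies and `J` blocks, so the DH
machinery reduces to reference orbitals plus scaled second-order terms.

## Solver parameters

| Parameter | Default | Units | Role |
| --- | --- | --- | --- |
| `omega_tol` | 1e-6 | Eh | stop when successive ω agree below this |
| `max_macro_iterations` | 50 | – | hard error (with diagnostics) beyond this |
| `damping` | 0.0 | – | mixing of the previous ω into the update |
| denominator guard | 1e-6 | Eh | hard error naming the (I, j, a) triple |
| metric drop threshold | 1e-10 | – | eigenvalue cutoff in `V^{-1/2}` |

The fixed point is strongly contractive in the physical regime (the
second-order shift is a tiny fraction of ω), so damping is off by default;
the converged ω is damping-independent to well within `omega_tol`.
Denominators are guarded by a hard error, not a level shift or regularizer:
silently shifted denominators would corrupt benchmark comparability, and a
singular denominator is a physical diagnosis (a 2h1p state degenerate with
the ionization) that the user should see.

**Root homing.** Eigenpairs are tracked across ω updates by eigenvector
overlap, not eigenvalue order, because near-degenerate core levels
(symmetry-equivalent atoms) reorder freely between iterations. All roots
iterate jointly and the eigenpairs of each root's matrix are matched to
roots one-to-one (maximum-overlap bipartite assignment); without the
matching constraint, two roots whose fold-in energies drift together in a
near-degenerate block can collapse onto the same eigenstate and silently
lose a solution. Degenerate cores are kept canonical (possibly
delocalized); no core-hole localization is performed, so all states of a
near-degenerate active block are computed together and reported as a set.

## Orbital partitioning

Selection of the active core supports explicit indices, an energy window,
and element K-edge selectors. Element selection assigns each MO to its
dominant atom (largest Mulliken-style population; when the backend supplies
no assignment it is computed from `|C|²` weights with an AO→atom map,
assuming orthonormal AOs — real Mulliken populations including overlap are
the backend's responsibility) and takes the deepest occupied MO per atom of
the element. Untargeted chemical-core orbitals (energy below −5 Eh by
default) are frozen, the conventional frozen-core rule, and this is
configurable (`freeze_other_cores=False`) since the trade-off between CVS
consistency and correlating other cores is a user decision. The partition
enforces: disjoint cover of all orbitals, nonempty active set, and every
active-core energy strictly below every inactive-occupied energy.

## The reference bundle

A bundle is a zip archive of named, row-major float64 `.npy` members (the
NumPy `.npz` container) plus a `metadata.json` member carrying the scalar
reference data and the declared shapes of the four `J` blocks. Orbitals are
ordered `[active cores | inactive occupied | other occupied | virtuals]`,
so the block shapes fix the partition. Round-trips are bit-exact; loading
validates declared shapes against array shapes and block-size consistency.
Bundles are produced at run time (by the `fixture` CLI command or a
backend); none are stored in the repository.

## Synthetic systems: what they emulate, what they do not

`generate_fixture` produces the inputs a converged reference plus MO-basis
density fitting would deliver: active-core energies near −10 Eh (a
second-row 1s scale) with ±0.1 Eh spread, inactive occupied in
[−1, −0.3] Eh, virtuals in [0.2, 2] Eh, and three-center tensors drawn as
`V^{1/2}·B` with `B` standard-normal at scale 0.1 over a random SPD metric.
The metric-consistent draw matters: a bare random draw is amplified by
`λ^{-1/2}` along weak metric directions, producing unphysically large
couplings. Two deliberate properties of these conditions:

* the energy windows keep every fold-in denominator bounded away from zero
  (|D| ≳ 0.3 Eh) for near-Koopmans ω, so the nonlinear fixed point is
  contractive and unique per root — fixtures exercise the solver, they do
  not park it on a shake-up resonance;
* the coupling scale keeps second-order shifts at the 0.01–0.2 Eh level,
  small against the ~9 Eh core-valence gap, mirroring the physical regime
  where second-order theory is meaningful.

Consequently, passing tests demonstrate the correctness of the
contractions, the spin adaptation, the density-fitting factorization and
the self-consistency loop — they do not demonstrate chemical accuracy on
real molecules, which depends on basis sets, auxiliary sets, relativistic
treatment and the reference orbitals, all owned by the SCF backend.

## Verification strategy

The independent oracle is written in **spin orbitals** precisely because
the production code is spin-adapted: agreement is a genuine check of the
`(2c − c′)` contractions and of the OS/SS split. The oracle assembles the
full symmetric Hamiltonian over the 1h ⊕ 2h1p space — singles block
`diag(−ε_I)`, diagonal doubles block `−(ε_I + ε_j − ε_a)`, coupling block
from antisymmetrized spin-orbital integrals with three spin cases per
spatial triple — and diagonalizes it once, no ω iteration: by the
block-elimination identity its core-dominated eigenvalues *are* the
self-consistent folded solutions. Spin scaling enters the oracle by
weighting the spin *cases* of the coupling block (`√c_os` on the two
opposite-spin cases, `√c_ss` on the same-spin case), a different route
from the production OS/SS decomposition. The agreement sweep (100 seeded
systems, N_act ≤ 3, N_inact ≤ 6, N_virt ≤ 6, N_aux ≤ 10; sizes chosen so
the dense space stays ≤ ~330 configurations and the whole sweep runs in
seconds on one CPU) observes deviations below 1e-12 Eh in both channels.

Further cross-checks: the perturbative energy against the diagonal
self-energy element of the same dense blocks; a one-auxiliary-channel toy
system small enough that every intermediate is hand-computable (couplings
−0.10 and −0.06, denominator exactly −1, correction −0.0152 Eh, SOS
correction −0.01768 Eh, fixed point ≈ 9.98502 Eh verified against a scalar
bisection); and an exact-fit system whose auxiliary index runs over the
full orbital-pair space, where density-fitted energies must coincide with
energies assembled from exact four-center integrals.

## Numerical choices and degenerate inputs

* Hartree everywhere internally; eV only at the reporting layer
  (1 Eh = 27.211386245988 eV, the single conversion point). Reports print
  0.01 eV precision; the JSON sidecar carries full precision.
* Orbital indexing is 0-based throughout the API; reports print both index
  and energy.
* The effective matrix is symmetrized as `(M + Mᵀ)/2`; asymmetry above
  1e-8 (possible only if the core-core DF block is asymmetric) emits a
  diagnostic warning rather than silently proceeding.
* Eigenvector signs are fixed by continuity with the previous iterate.
* Mulliken-style element assignment breaks ties toward the lowest atom
  index, making element selection deterministic.
* Occupied energies above virtual energies trigger a warning, not an error
  (the ordering between blocks is not assumed); the CVS ordering between
  active-core and inactive-occupied energies *is* enforced.

## Known limitations

* The SCF, exchange-correlation functionals, scalar-relativistic
  (X2C-type) one-electron Hamiltonians and auxiliary-basis generation live
  behind the backend adapter; the shipped pyscf adapter covers nonrelativistic
  HF/KS with standard auxiliary bases, and results on real molecules
  inherit every limitation of the backend's numerics.
* Valence ionization (no CVS), core-excited states (X-ray absorption),
  open-shell references and localized core-hole (ΔSCF-style) treatments
  are out of scope.
* The singles weight is the only spectroscopic diagnostic; Dyson orbitals
  and spectroscopic factors are not computed.
* Peak-separation statistics use population normalization for the SD of
  relative errors and sample normalization for the SD of absolute errors;
  both conventions are stated where they are computed, since mixing them
  silently would make tabulated comparisons irreproducible.
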