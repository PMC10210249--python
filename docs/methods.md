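# Methods

## Scope and model

`coreadc` computes K-edge (1s core-level) excitation energies and
oscillator strengths of small closed-shell molecules with the strict
second-order algebraic-diagrammatic construction, ADC(2), under the
core-valence separation (CVS), using density fitting (DF) throughout, and
optionally compressing the working dimensions with natural auxiliary
functions (NAFs) and state-specific frozen virtual natural orbitals
(VNOs).  The target quantity of the package is not primarily the absolute
spectrum but the *truncation error*: how much the compressed (reduced-cost)
calculation deviates from the canonical DF-CVS-ADC(2) result on the same
footing.

All electronic-structure machinery is self-contained: a
McMurchie-Davidson Gaussian integral engine (overlap, kinetic, nuclear
attraction, dipole, dense four-center ERIs for validation, and the two-
and three-center Coulomb integrals used in production), a restricted
Hartree-Fock solver with DIIS, and the correlated modules described
below.  Internal units are Hartree/bohr; reported energies are eV
(1 Hartree = 27.211386 eV) and geometries Angstrom.

## CVS-ADC(2) in folded (effective-Jacobian) form

The strict ADC(2) secular problem over singles (1h1p) and doubles (2h2p)
configurations is folded into the singles space.  With `I, J` active-core
occupied, `i, j` inactive occupied, `a, b, c, d` virtual and `k, l`
generic correlated occupied orbitals, the effective sigma vector acting
on a spin-adapted singlet core-hole singles vector `r_{Ia}` is

    sigma(r, w) = sigma_CIS(r) + sigma_GS(r) + sigma_D(r, w)

* `sigma_CIS`: the singlet CVS-CIS part,
  `(e_a - e_I) r_{Ia} + sum_{Jb} [2(Ia|Jb) - (IJ|ab)] r_{Jb}`.
* `sigma_GS`: the omega-independent second-order terms built from
  ground-state MP2 amplitudes `t_{kl}^{cd} = (kc|ld)/(e_k+e_l-e_c-e_d)`:
  a symmetrized virtual-virtual intermediate `X_ab`, an active-core
  occupied-occupied intermediate `Y_IJ`, and the non-diagonal
  `(2t - t)(2K - K)` cross contraction.  `X` and `Y` are accumulated
  pair-wise; the full amplitude tensor is never stored (only the small
  slice with one active-core index is kept for the cross terms).
* `sigma_D`: the doubles fold.  CVS doubles carry exactly one active-core
  occupied index.  Their coefficients

      B_{Ij}^{cd}(w) = [ (I~c|jd) + (Ic|j~d) ] / (w + e_I + e_j - e_c - e_d)

  (tilde: index dressed by `r`, a particle term minus a hole term) are
  built on the fly per state and contracted immediately; the denominators
  contain the excitation energy `w`, which makes the eigenproblem
  nonlinear.

The closed-shell spin adaptation of every contraction was derived by
explicit spin summation and verified numerically, element by element,
against an independent spin-orbital formulation (see Validation).

### Nonlinear solver

The pseudo-eigenvalue problem `sigma(r, w) = w r` is solved state by
state: CVS-CIS is solved once in the global space (dense diagonalization
below 60 singles, block Davidson with a padded guess block above), and
each CIS root seeds its own macro-iteration in which (i) a small Davidson
subspace is rebuilt at the current `w`, (ii) the root is homed by maximal
overlap with the CIS guess, (iii) `w` is updated from the Rayleigh
quotient, and (iv) the iteration is DIIS-accelerated (depth 6) on the
residual vectors.  Convergence requires `|w - theta| < 1e-6` Hartree and
residual norm `< 1e-5` (defaults; the acceptance checks tighten these).
A converged state whose overlap with its CIS guess falls below 0.5 is
flagged with a warning, since the VNO selection quality degrades in that
regime.  Exact hits on a doubles pole raise an explicit error naming the
configuration.

## Density fitting

Four-center ERIs are factorized as `(pq|rs) = sum_Q J^Q_pq J^Q_rs` with
`J = I V^(-1/2)`; the metric inverse square root discards eigenvalues
below 1e-10 (projecting numerically dependent fitting directions).  `J`
is stored with the auxiliary index leading, in MO-group blocks (cc, co,
cv, oo, ov, vv; frozen cores never stored), so a NAF rotation is one
matrix product per block.  At the problem sizes this package targets no
batching over the virtual index is needed; the blocks fit comfortably in
memory.

The auxiliary basis is generated per element from the orbital basis as an
even-tempered geometric ladder (ratio beta = 2.0) spanning the full
product-exponent range for every angular momentum reachable by orbital
products, extended by one unit of angular momentum (so hydrogen receives
p fitting functions for bond-centered products) and capped at d.  The
steep core s-product exponents are deliberately retained - the probed
states have 1s holes.  Auxiliary d shells use the six Cartesian
components; the mild redundancy this creates is handled by the metric
cutoff.  On the minimal-basis fixtures this fit reproduces dense-ERI
CVS-CIS excitation energies to better than 2 meV.

## NAF compression

`W = sum_pq J_pq (x) J_pq` is diagonalized over the auxiliary index;
off-diagonal MO-group blocks enter twice (both `(p,q)` and `(q,p)` appear
in the full integral list).  The eigenvalues of `W` are squared singular
values of the unfolded `J`; NAFs with singular value below `eps_NAF`
(default 0.1 au) are dropped.  The Frobenius norm of the discarded part
of `J` equals the square root of the dropped eigenvalue sum, which the
tests assert.  The truncation is applied twice: globally to the canonical
integral list, and per state in the truncated VNO basis, both with the
same cutoff; when the VNO step does not truncate, the second NAF pass
keeps exactly the first pass's count (the semicanonical rotation is
unitary).

## State-specific VNOs

For each CIS root the virtual-virtual block of a state-averaged
one-particle density `D = (D_MP2 + D_CVS-CIS(D))/2` is diagonalized.

* `D_MP2` is the unrelaxed MP2 density
  `D_ab = 2 sum_{ijc} t_{ij}^{ac} (2 t_{ij}^{bc} - t_{ij}^{cb})`
  over the frozen-core amplitude set.
* `D_CVS-CIS(D)` is the CIS outer product `sum_I r_Ia r_Ib` (trace 1 for
  a normalized singlet) plus the quadratic contribution of the doubles
  coefficients `B(w_CIS)`; both terms use the same CVS restriction as the
  secular problem.

Eigenvectors with `|occupation| >= eps_VNO` (default 7.5e-5) are kept;
ranking is by magnitude because the CIS(D) part can contribute slightly
negative eigenvalues.  The kept block is semicanonicalized (the diagonal
virtual Fock rediagonalized) so that all orbital-energy denominators
remain valid; this is what makes the thresholds-to-zero limit recover the
canonical energies to 1e-8 Hartree, the central correctness property of
the compression.  The occupied space is never truncated.

The averaging makes one subspace serve the ground-state amplitudes and
the excited state simultaneously, at the cost of strict inter-state
orthogonality - acceptable here because only ground-to-excited moments
are computed.

## Oscillator strengths

Dipole-length gauge, `f = (2/3) w |mu|^2`.  The transition moment couples
the MP2-correlated ground state to the (singles + doubles) excited state
and contains:

1. the zeroth-order term `sqrt(2) sum_Ia r_Ia mu_Ia`;
2. the first-order intensity-borrowing term: MP1 doubles contracted with
   `r`, activating valence occupied -> virtual dipole elements;
3. the MP2-density renormalization `-1/2 (rho_oo r + r rho_vv)` of the
   singles amplitudes;
4. the doubles coefficients `B(w)` contracted with the MP1 doubles
   through the occupied-occupied and virtual-virtual dipole blocks,
   including the ground-state-dipole overlap correction
   `- <0|mu|0><Psi_0^(1)|B>`.

Terms 1-2 are the complete moment through first order; of the
second-order contributions, the remaining pure-singles terms (from the
second-order ground-state wave function beyond the density
renormalization) are omitted.  The implemented density is traceless by
construction, so `f` is rigorously origin-independent (verified by a 5 A
rigid translation) and sums over degenerate components are rotationally
invariant.  Statistics on `f` follow the convention of including only
transitions with `f > 0.015`.

## Orbital partition

Active cores are the occupied canonical MOs with summed Mulliken
population >= 0.5 on the selected element's steepest contracted s
function - a population criterion, not an energy-ordering one, so two
equivalent atoms yield two active cores regardless of accidental
degeneracies.  The default frozen-core policy freezes the 1s orbitals of
other first-row atoms everywhere (ground-state amplitudes and the doubles
space); `mp2-only` and `none` policies are available.  Deep-core
delocalization between equivalent atoms is physical: the two C2H4 C
K-edge components are split by the (small) 1sigma_g/1sigma_u interaction,
while states in degenerate point-group irreps (NH3 e, CH4 t2) are exactly
degenerate and are used as the symmetry benchmarks.

## Validation methodology

Because the package carries its own integral and SCF engines, the test
suite leans on independent, brute-force references:

* integrals against symbolic/closed forms, a 3D quadrature oracle, the
  classic tabulated H2/STO-3G values, and center-derivative identities;
* HF/FCI against literature energies (H2O/STO-3G RHF, H2/STO-3G FCI);
* a second-quantized determinant engine (explicit creation/annihilation
  bookkeeping, no transcribed matrix-element formulas) that supplies CI
  blocks, full CI, S^2 classification and one-body transition moments;
* the decisive order test: scaling the fluctuation potential by lambda,
  the explicit ADC(2) matrix must reproduce FCI singlet excitation
  energies to O(lambda^3) - this pins every sign and factor of the
  second-order secular matrix;
* the folded production path is required to agree with the explicit
  (singles + doubles) matrix to 1e-8 Hartree on minimal fixtures, and
  every closed-shell contraction (sigma pieces, densities, moment terms)
  was matched element-wise against its spin-orbital counterpart.

## Problem sizes and what the tests do and do not show

The built-in suite (H2O, NH3, CO, HF, CH4, C2H4, H2CO at the
split-valence double-zeta basis, three states per C/N/O edge) was chosen
so the complete acceptance sweep runs in minutes on one CPU.  At this
scale the NAF truncation is strong (roughly 25-30% of fitting functions
retained at the default cutoff) while the VNO occupation spectra of the
small virtual spaces mostly lie above 7.5e-5, so the default VNO step
truncates little - consistent with the trend that small systems compress
least.  Consequently the measured truncation errors (MAE of order 0.01 eV,
MRE of order 1e-3) sit far below the method's error bounds; the
monotonicity of the error under threshold tightening is exercised with a
loosened eps_VNO where the truncation demonstrably bites.  Behavior that
only emerges with large diffuse basis sets (Rydberg-dominated VNO
selection stress, deep compression plateaus, wall-clock speedups) is
outside what these fixtures can probe.

## Known limitations

* Closed-shell restricted references only; singlet final states only.
* Strict ADC(2); the extended variant's first-order doubles-doubles
  block is not implemented.
* Orbital bases: built-in STO-3G and 6-31G for H-Ne (s/p), auxiliary
  generation up to d; no f functions.
* Transition moments between two core-excited states are not available.
* Absolute K-edge energies at a double-zeta basis carry the usual
  basis-set and relativistic errors (no relativistic corrections); the
  package's statements are about reduced-vs-canonical agreement.
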