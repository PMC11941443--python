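# Methods

## The model

`spinshield` simulates a minimal open-quantum-system model of entanglement
protection in geometrically structured spin clusters, motivated by the
phosphate group inside a Posner cluster: a protected central spin-1/2 (the
phosphorus-nucleus analogue) surrounded by `N` buffer spins (oxygen
analogues) that talk to the thermal environment on its behalf.

One cluster of `N + 1` spins evolves under the XX Hamiltonian (hbar = 1)

    H = sum_i (omega/2) sigma_z^(i)
      + sum_{unordered pairs {i,j}} g_ij (sigma_x^(i) sigma_x^(j) + sigma_y^(i) sigma_y^(j)),

with `g_1j = g` between the central spin (site 1) and every buffer, and
`g_ij = g A_ij` inside the buffer block, where `A` is a binary adjacency
matrix. Two extremes of `A` are built in: *vanishing* (star topology — no
buffer-buffer bonds) and *maximal* (complete buffer graph; for `N = 5` the
planar embedding around the central spin forbids one bond, leaving the
complete graph minus the edge between buffers 1 and 5). Arbitrary binary
adjacencies are accepted as custom geometries.

The pair sum runs over unordered pairs, each bond counted once. This is the
convention under which one XX bond moves a single excitation with amplitude
`G = 2g`, the collective coupling the dressed-picture analysis is built on;
counting ordered pairs would silently double every coupling.

Basis convention: `sigma_z = |0><0| - |1><1|`, so `|0>` is the excited state
under `+omega/2 sigma_z` and the lowering operator is `sigma_minus = |1><0|`.
All code and tests use this convention consistently.

Dissipation is local and thermal: every buffer spin (never the central spin)
is damped at rate `gamma (1 + n)` and pumped at `gamma n`, with
`n = 1/(e^{beta omega} - 1)` the Planck occupation at the spin resonance.
The master equation is

    d rho/dt = -i [H, rho]
             + sum_buffers gamma (1+n) D[sigma_minus] + gamma n D[sigma_plus],

`D[L] rho = L rho L^dag - (1/2){L^dag L, rho}`. Detailed balance of the two
rates fixes the single-qubit Gibbs state as the local fixed point, which the
tests verify. The local (rather than global) dissipator is an assumption of
the model, valid for weakly coupled buffers; it is not re-derived here.

The entanglement experiment takes two identical, mutually uncoupled clusters
whose central spins share the Bell state `(|01> + |10>)/sqrt(2)` while all
`2N` buffers start thermal. Entanglement between the central spins is
measured by the negativity `N(rho) = sum |negative PT eigenvalues|` and the
logarithmic negativity `E_N = log2(2 N + 1)`; the survival time `t1` is the
earliest grid time after which `E_N` never again reaches a threshold
(default `1e-4`).

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `omega` | spin resonance frequency (sets the energy/time scale) | 1 | scale choice |
| `g` | exchange coupling, central-buffer and buffer-buffer | 0.05 | `g << omega`: exchange slow against precession |
| `gamma` | buffer-bath rate | 0.005 | `gamma << g`: weak damping, the regime where the local dissipator is justified and geometry effects are visible |
| `beta` | bath inverse temperature | 5 | cold baths (`n(omega) = 0.0068`); see below |
| `t_max`, `n_steps` | output grid | 5000, 2000 | covers the full decay of `E_N` past the `1e-4` threshold for every shipped geometry |

All quantities are dimensionless with `hbar = k_B = 1`; times are in units
of `1/omega`.

The temperature deserves a note. At `beta omega = 5` the shipped defaults
give survival times of order 10^3 — `t1 = (1246, 1201, 1150, 1113)` for the
star geometries and `(1510, 2015, 2554, 1876)` for the connected ones,
N = 2..5 — with the connected network winning at every N and the tetrahedral
`N = 4` complete network holding the overall record. At warmer baths
(`beta omega = 2`, `n = 0.157`) thermal pumping shortens every survival time
about tenfold and blurs the geometry ranking; the protection effect this
package exists to study is a cold-bath phenomenon. `beta = inf` is accepted
and means ground-state buffers.

## Numerics

The Liouvillian is time independent, so trajectories are computed by the
exact action of the matrix exponential on the row-major-vectorized density
matrix (`scipy.sparse.linalg.expm_multiply` on a sparse superoperator),
not by an ODE stepper: there is no truncation-error tolerance to tune, and
trace/positivity hold to near machine precision at every output time.

Integration is performed in the frame rotating at `omega`. The uniform
Zeeman term commutes with the XX coupling, and the jump operators are
eigenoperators of the rotation, so the dissipator is frame invariant; the
precession is restored analytically on the output states. This removes the
fast `omega` oscillation from the integrator's workload over horizons of
order 10^3-10^4. Lab-frame integration is retained (`frame="lab"`) and
agrees with the rotating frame to 1e-8 in the tests.

Because the two clusters are uncoupled and the buffers start thermal, the
joint 2(N+1)-qubit dynamics factorizes exactly: the central-pair state is
`(Lambda_t x Lambda_t)` applied to the Bell state, with `Lambda_t` the
one-cluster central-spin channel. The default compute path extracts
`Lambda_t` once per geometry as a Choi trajectory (ancilla trick: evolve an
ancilla maximally entangled with the central spin, trace out the buffers)
and composes channels by tensor contraction. This reduces the worst shipped
case from 12 qubits (density dimension 4096) to 7 (dimension 128). The
brute-force joint integration is kept as a correctness oracle, guarded to
`N <= 3`, and the two paths agree to trace distance < 1e-6 (in practice
~1e-15) on every tested grid.

Choi convention: `J = sum_ij |i><j| (x) Lambda(|i><j|)`, input factor first,
trace 2; complete positivity = PSD of `J`, trace preservation =
`tr_out J = I`. Both are validated along every extracted trajectory.

Other numerical choices:

- survival time uses the *last-crossing* rule (earliest grid time after
  which the metric never again reaches threshold) because non-Markovian
  revivals can re-cross a first-crossing time; first-crossing is available
  as an option. `t1` always lies on the output grid, so its resolution is
  the grid step (2.5 time units at the defaults).
- the BLP non-Markovianity witness is the sum of positive increments of the
  trace distance on the output grid — no derivative estimation, no smoothing
  parameters; it is zero iff the sampled curve is monotone non-increasing.
- entropies treat eigenvalues below 1e-12 as zero (`0 log 0 = 0`).
- degenerate eigenspaces in the dressed picture are rotated by a Householder
  reflection so the coupling vector's projection concentrates on one basis
  vector per eigenspace; eigenvector signs are fixed by making each column's
  largest-magnitude entry positive. Reported coupling *magnitudes* are
  convention independent; printed signs are not.
- the edgeless buffer graph skips the dressing entirely (`U = I`): with a
  diagonal buffer block the dressed picture *is* the original picture.
- `biorthogonal_eigensystem` guards against (near-)defective input by the
  condition number of the right-eigenvector matrix (limit 1e12) and
  explicitly re-biorthogonalizes left/right pairs inside degenerate
  eigenvalue groups; conjugate-pair matching for thermal states uses a
  relative tolerance of 1e-9.

## The dressed picture

Restricted to the single-excitation sector the Hamiltonian is the
`(N+1) x (N+1)` symmetric matrix with first row `(omega, G, ..., G)` and
buffer block `H' = omega I + G A`. Diagonalizing `H' = U D U^T` defines
non-interacting *dressed* buffer modes. For the complete graph the uniform
vector is the top adjacency eigenvector (eigenvalue `N - 1`), so the central
spin couples to exactly one dressed mode, with strength `sqrt(N) G`
(1.41 G, 1.73 G, 2.00 G for N = 2, 3, 4) at frequency `omega + (N-1) G`;
the other `N - 1` modes decouple. For the `N = 5` complete-minus-one-edge
network two modes stay coupled, with magnitudes
`sqrt(5/2 + 13 sqrt(7)/14) G = 2.2264 G` and `0.2079 G` (closed form checked
against direct diagonalization), at frequencies `omega + 2(1 +- sqrt(7)) g`.

The interpretation: connectivity concentrates N weak, independently damped
decay channels into one strongly coupled dressed mode that is also detuned
from the central spin by `(N-1) G`. The central spin's leakage into the
dissipative buffer block shrinks as the detuning grows faster than the
coupling, which is how the complete tetrahedral network (N = 4) wins the
survival sweep. The transformation is exact only in the single-excitation
sector; the package confines quantitative dressed-picture claims to that
sector and exposes the many-body transformed operators only descriptively.

## Non-Markovianity diagnostics

The backflow experiment evolves the two orthogonal central-spin states
`|+>` and `|->` (buffers thermal) and tracks the trace distance of the
reduced central-spin states. `D(0) = 1`; any later increase witnesses
information backflow. Two findings of the implementation worth recording:

- reducing to the whole cluster instead of the central spin gives an
  identically zero witness: the full cluster evolves under an exact Lindblad
  semigroup, and trace distance is contractive under it. The central-spin
  reduction is therefore the only informative choice.
- in the weak-damping regime the *summed* backflow witness decreases
  monotonically with N among the connected geometries (the dressed mode's
  exchange fraction falls as coupling `sqrt(N) G` loses to detuning
  `(N-1) G`), while the distinguishability *envelope* decays more slowly for
  larger N. Connectivity shows up in these diagnostics as slower information
  loss, not as a larger cumulative backflow sum; the two orderings invert
  only near `gamma = 4g`, where the weakly coupled dressed modes become
  overdamped and the model's weak-damping assumption no longer holds.

## Coherence measures

For delocalization questions (the exciton-transport side of the package) the
l1 norm of coherence `sum_{k != k'} |rho_kk'|` and the relative entropy of
coherence `S(rho_diag) - S(rho)` (base 2) are provided in any reference
basis, together with the inter-block decomposition
`C[rho_AB] - C[rho_A] - C[rho_B]`. The biorthogonal module implements
thermal states `sum_E e^{-beta E} |E_R><E_L| / (c_E Z)` of non-Hermitian
effective Hamiltonians and site-probability maps, including the cautionary
construction where two sites both carry population while the off-diagonal
element connecting them is exactly zero — population maps do not witness
delocalization; coherence measures do.

## What the simulations do and do not show

The model is a toy: identical spin-1/2 sites, a single coupling magnitude,
local Markovian baths, no inter-cluster interaction, no chemistry. Passing
tests show that the *mechanism* — buffer connectivity concentrating and
detuning the dissipative coupling, thereby extending entanglement survival —
is real within the model, robust to the integration path, and exactly
explainable in the dressed picture. They say nothing about real phosphate
groups: nuclear dipolar couplings are heterogeneous, baths are structured,
and cluster geometries fluctuate. Survival times are reported in units of
`1/omega` at a representative parameter point; only their orderings across
geometries, not their absolute values, are meaningful claims.

## Problem sizes

Shipped experiments use density dimensions up to 128 (channel extraction for
N = 5) and 65536-dimensional superoperators for the N = 3 joint oracle; the
default sweep (8 geometries, 2000 output points to t = 5000) completes in
about two minutes on one CPU, and the full test suite in a few minutes.
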