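"""Scalar diagnostics on states and trajectories.

Entanglement is quantified by the negativity ``N(rho) = sum_i |lambda_i|``
over the negative eigenvalues of the partial transpose, and the logarithmic
negativity ``E_N = log2(2 N + 1)``; the *survival time* ``t1`` of a decaying
``E_N(t)`` trajectory is the earliest grid time after which the value never
again exceeds a threshold (default 1e-4).  The last-crossing rule is the
default because non-Markovian revivals can push ``E_N`` back above threshold
after a first crossing; a first-crossing rule is available.

Non-Markovianity is witnessed in the BLP (Breuer-Laine-Piilo) sense: the
trace distance between two initially orthogonal central-spin states
(``|+>`` and ``|->``) is monotonically contractive under Markovian dynamics,
so any increase signals information backflow from the buffer network.  The
scalar witness reported here is the sum of positive increments of the
distance on the output grid.

Coherence in a reference basis is measured by the l1 norm (sum of
off-diagonal magnitudes) and the relative entropy of coherence
``S(rho_diag) - S(rho)`` (base-2).  The inter-block decomposition
``C[rho_AB] - C[rho_A] - C[rho_B]`` isolates coherence that lives across a
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ClusterGeometry, DensityOperator, ModelParams, plus_minus_states, thermal_qubit
from .operators import partial_trace

__all__ = [
    "MetricTrajectory",
    "SurvivalRecord",
    "negativity",
    "log_negativity",
    "survival_time",
    "trace_distance",
    "nonmarkovianity_trajectory",
    "blp_witness",
    "l1_coherence",
    "relative_entropy_coherence",
    "block_coherence_decomposition",
]

ENTROPY_EIG_CUTOFF = 1e-12
DEFAULT_SURVIVAL_THRESHOLD = 1e-4


@dataclass
class MetricTrajectory:
    """A scalar metric sampled on an ascending time grid."""

    times: np.ndarray
    values: np.ndarray
    metric_name: str = "metric"
    threshold: Optional[float] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metric values must be finite")

    def __len__(self):
        return len(self.times)


@dataclass
class SurvivalRecord:
    """Survival time of entanglement for one geometry.

    ``t1`` is None when the metric still exceeds the threshold at the end of
    the simulated horizon (survival undetermined within the horizon).
    """

    n_buffer: int
    connectivity_label: str
    t1: Optional[float]
    threshold: float = DEFAULT_SURVIVAL_THRESHOLD


def _as_matrix(state) -> np.ndarray:
    if isinstance(state, DensityOperator):
        return state.matrix
    return np.asarray(state, dtype=complex)


def partial_transpose(state, dims=(2, 2)) -> np.ndarray:
    """Partial transpose on the second subsystem of a bipartite state."""
    rho = _as_matrix(state)
    da, db = dims
    if rho.shape != (da * db, da * db):
        raise ValueError("state shape does not match bipartition dims")
    t = rho.reshape(da, db, da, db)
    return t.transpose(0, 3, 2, 1).reshape(da * db, da * db)


def negativity(state, dims=(2, 2), psd_tol: float = 1e-8) -> float:
    """Sum of |negative eigenvalues| of the partial transpose."""
    rho = _as_matrix(state)
    lo = np.linalg.eigvalsh((rho + rho.conj().T) / 2).min()
    if lo < -psd_tol:
        raise ValueError(f"input is not PSD (min eigenvalue {lo:.3g})")
    eigs = np.linalg.eigvalsh(partial_transpose(rho, dims))
    return float(-eigs[eigs < 0].sum())


def log_negativity(state, dims=(2, 2)) -> float:
    """Logarithmic negativity log2(2 N(rho) + 1)."""
    return float(np.log2(2.0 * negativity(state, dims) + 1.0))


def survival_time(trajectory: MetricTrajectory,
                  threshold: float = DEFAULT_SURVIVAL_THRESHOLD,
                  rule: str = "last",
                  geometry: Optional[ClusterGeometry] = None) -> SurvivalRecord:
    """Earliest grid time after which the metric stays below ``threshold``.

    ``rule="last"`` (default): t1 is the first grid time from which the value
    never again reaches the threshold within the horizon -- robust to
    non-Markovian revivals.  ``rule="first"``: t1 is the first grid time at
    which the value drops below the threshold.
    """
    t = trajectory.times
    v = trajectory.values
    above = v >= threshold
    if rule == "last":
        if above[-1]:
            t1 = None
        elif not above.any():
            t1 = float(t[0])
        else:
            last_above = np.nonzero(above)[0][-1]
            t1 = float(t[last_above + 1])
    elif rule == "first":
        below = np.nonzero(~above)[0]
        t1 = float(t[below[0]]) if len(below) else None
    else:
        raise ValueError("rule must be 'last' or 'first'")
    meta = geometry if geometry is not None else getattr(trajectory, "geometry", None)
    n_buffer = getattr(meta, "n_buffer", -1)
    label = getattr(meta, "connectivity_label", "unknown")
    return SurvivalRecord(n_buffer=n_buffer, connectivity_label=label,
                          t1=t1, threshold=threshold)


def trace_distance(a, b) -> float:
    """D(a, b) = (1/2) ||a - b||_1 (half the sum of singular values)."""
    am, bm = _as_matrix(a), _as_matrix(b)
    if am.shape != bm.shape:
        raise ValueError("trace distance requires equal shapes")
    diff = am - bm
    if np.abs(diff - diff.conj().T).max() < 1e-10:
        vals = np.abs(np.linalg.eigvalsh(diff))
    else:
        vals = np.linalg.svd(diff, compute_uv=False)
    return float(0.5 * vals.sum())


def nonmarkovianity_trajectory(geometry: ClusterGeometry, params: ModelParams,
                               times, reduce_to: str = "central") -> MetricTrajectory:
    """Trace distance D(t) between the evolutions of the two initially
    orthogonal central-spin states |+> and |-> (buffers thermal).

    ``reduce_to="central"`` compares the reduced central-spin states
    (default); ``"cluster"`` compares the full cluster states.
    """
    from .dynamics import evolve_cluster  # local import avoids cycle

    if reduce_to not in ("central", "cluster"):
        raise ValueError("reduce_to must be 'central' or 'cluster'")
    plus, minus = plus_minus_states()
    th = thermal_qubit(params).matrix
    trajs = []
    for central0 in (plus, minus):
        rho0 = central0
        for _ in range(geometry.n_buffer):
            rho0 = np.kron(rho0, th)
        trajs.append(evolve_cluster(DensityOperator(rho0), geometry, params, times))
    dims = [2] * geometry.n_sites
    vals = np.empty(len(trajs[0]))
    for k in range(len(vals)):
        a, b = trajs[0].states[k], trajs[1].states[k]
        if reduce_to == "central":
            a = partial_trace(a, [0], dims)
            b = partial_trace(b, [0], dims)
        vals[k] = trace_distance(a, b)
    return MetricTrajectory(trajs[0].times, vals, metric_name="trace_distance")


def blp_witness(trajectory: MetricTrajectory) -> float:
    """Sum of positive increments of the trajectory on its grid.

    Zero iff the sampled trajectory is monotone non-increasing; positive
    values witness information backflow (non-Markovianity) in the BLP sense.
    """
    inc = np.diff(trajectory.values)
    return float(inc[inc > 0].sum())


def _to_basis(state, basis=None) -> np.ndarray:
    rho = _as_matrix(state)
    if basis is None:
        return rho
    b = np.asarray(basis, dtype=complex)
    if b.shape != rho.shape:
        raise ValueError("basis shape does not match state")
    return b.conj().T @ rho @ b


def l1_coherence(state, basis=None) -> float:
    """Sum of off-diagonal magnitudes in the reference basis.

    ``basis`` is a unitary whose *columns* are the reference basis vectors;
    None means the computational basis.
    """
    rho = _to_basis(state, basis)
    return float(np.abs(rho).sum() - np.abs(np.diag(rho)).sum())


def _von_neumann_entropy(rho: np.ndarray) -> float:
    eigs = np.linalg.eigvalsh((rho + rho.conj().T) / 2)
    eigs = eigs[eigs > ENTROPY_EIG_CUTOFF]
    return float(-(eigs * np.log2(eigs)).sum())


def relative_entropy_coherence(state, basis=None) -> float:
    """S(rho_diag) - S(rho) in bits, rho_diag the dephased state."""
    rho = _to_basis(state, basis)
    diag = np.diag(np.diag(rho).real).astype(complex)
    return _von_neumann_entropy(diag) - _von_neumann_entropy(rho)


_COHERENCE_MEASURES = {
    "l1": l1_coherence,
    "relative_entropy": relative_entropy_coherence,
}


def block_coherence_decomposition(state, dims, block_a, measure: str = "l1"):
    """Coherence of a bipartite state, its marginals, and the inter-block part.

    Parameters
    ----------
    state : density matrix on subsystems with dimensions ``dims``.
    dims : sequence of subsystem dimensions.
    block_a : indices of the subsystems forming block A; the complement is
        block B.  Both blocks must be nonempty.
    measure : ``"l1"`` or ``"relative_entropy"``.

    Returns ``(C_AB, C_A, C_B, inter)`` with ``inter = C_AB - C_A - C_B``,
    all in the computational product basis.
    """
    if measure not in _COHERENCE_MEASURES:
        raise ValueError(f"unknown coherence measure {measure!r}")
    rho = _as_matrix(state)
    dims = list(dims)
    block_a = sorted(set(block_a))
    block_b = [i for i in range(len(dims)) if i not in block_a]
    if not block_a or not block_b:
        raise ValueError("both blocks must be nonempty")
    fn = _COHERENCE_MEASURES[measure]
    c_ab = fn(rho)
    c_a = fn(partial_trace(rho, block_a, dims))
    c_b = fn(partial_trace(rho, block_b, dims))
    return c_ab, c_a, c_b, c_ab - c_a - c_b
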