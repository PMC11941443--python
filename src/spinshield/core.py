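"""Model construction for a single spin cluster and the two-cluster experiment.

A cluster is one central spin-1/2 (the protected qubit, a phosphorus-nucleus
analogue) surrounded by ``N`` buffer spins (oxygen analogues).  The central
spin couples to every buffer at strength ``g``; buffer-buffer couplings are
``g`` or 0 according to a binary adjacency matrix.  Two connectivity extremes
matter: *vanishing* (star topology, no buffer-buffer edges) and *maximal*
(complete buffer graph for ``N <= 4``; for ``N = 5`` the planar embedding
around the central spin forbids one edge, giving the complete graph on five
vertices minus the edge between buffers 1 and 5 in 1-based buffer-local
numbering).

The Hamiltonian of a cluster is the XX model

    H = sum_i (omega/2) sigma_z^(i)
      + sum_{pairs {i,j}} g_ij (sigma_x^(i) sigma_x^(j) + sigma_y^(i) sigma_y^(j)),

where the pair sum runs over *unordered* pairs, each counted once.  This is
the reading consistent with the single-excitation coupling G = 2g used by the
dressed-picture analysis; an ordered-pair sum would double every coupling.

Sites of one cluster are ordered central first, then buffers; in the
two-cluster experiment cluster A's sites come fully before cluster B's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .operators import (
    SIGMA_X,
    SIGMA_Y,
    SIGMA_Z,
    embed,
    partial_trace,
)

__all__ = [
    "ModelParams",
    "ClusterGeometry",
    "DensityOperator",
    "build_geometry",
    "build_hamiltonian",
    "thermal_qubit",
    "initial_cluster_pair_state",
    "bell_state",
    "plus_minus_states",
    "adjacency_to_csv",
    "adjacency_from_csv",
]

HERMITICITY_TOL = 1e-10
TRACE_TOL = 1e-8
PSD_TOL = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the cluster model (hbar = k_B = 1).

    Parameters
    ----------
    omega : float
        Spin resonance frequency (dimensionless energy); must be positive.
    g : float
        Coupling constant for both central-buffer and buffer-buffer bonds.
    gamma : float
        Bath coupling rate, homogeneous across buffer spins.  The central
        spin is never directly damped.
    beta : float
        Inverse temperature of the local baths.  ``numpy.inf`` is accepted
        and means zero temperature (ground-state buffers, n(omega) = 0).

    The defaults (omega = 1, g = 0.05, gamma = 0.005, beta = 5) sit in the
    weak-damping regime gamma << g << omega where the local thermal
    dissipator is justified, and produce central-pair entanglement survival
    times of order 10^3 dimensionless time units.
    """

    omega: float = 1.0
    g: float = 0.05
    gamma: float = 0.005
    beta: float = 5.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.g < 0:
            raise ValueError("g must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def n_planck(self) -> float:
        """Planck occupation n(omega) = 1/(exp(beta*omega) - 1).

        The beta -> infinity (zero temperature) limit is 0; beta = 0 is the
        infinite-temperature limit where n diverges, which is rejected.
        """
        if np.isinf(self.beta):
            return 0.0
        x = self.beta * self.omega
        if x <= 0:
            raise ValueError("Planck occupation diverges at beta = 0")
        return 1.0 / np.expm1(x)


@dataclass(frozen=True)
class ClusterGeometry:
    """Central spin plus ``n_buffer`` buffer spins with binary buffer adjacency."""

    n_buffer: int
    buffer_adjacency: np.ndarray
    connectivity_label: str = "custom"

    def __post_init__(self):
        a = np.asarray(self.buffer_adjacency)
        if a.shape != (self.n_buffer, self.n_buffer):
            raise ValueError("adjacency shape does not match n_buffer")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(a, (0, 1))):
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "buffer_adjacency", a.astype(np.int64))

    @property
    def n_sites(self) -> int:
        """Cluster size N + 1 (central spin + buffers)."""
        return self.n_buffer + 1

    @property
    def n_edges(self) -> int:
        """Number of buffer-buffer edges."""
        return int(self.buffer_adjacency.sum()) // 2


@dataclass
class DensityOperator:
    """A labelled density matrix on a tensor product of qubits."""

    matrix: np.ndarray
    site_labels: list = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("density matrix must be square")
        if not self.site_labels:
            n = int(round(np.log2(m.shape[0])))
            self.site_labels = [f"q{i}" for i in range(n)]
        if 2 ** len(self.site_labels) != m.shape[0]:
            raise ValueError("site_labels inconsistent with matrix dimension")
        self.matrix = m

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def validate(self, herm_tol=HERMITICITY_TOL, trace_tol=TRACE_TOL, psd_tol=PSD_TOL):
        """Raise if the matrix is not a density operator within tolerance."""
        m = self.matrix
        if np.abs(m - m.conj().T).max() > herm_tol:
            raise ValueError("density matrix is not Hermitian within tolerance")
        if abs(np.trace(m) - 1.0) > trace_tol:
            raise ValueError("density matrix trace differs from 1")
        lo = np.linalg.eigvalsh((m + m.conj().T) / 2).min()
        if lo < -psd_tol:
            raise ValueError(f"density matrix has negative eigenvalue {lo:.3g}")
        return self

    def reduce_to(self, labels) -> "DensityOperator":
        """Partial trace keeping only the sites named in ``labels``."""
        keep = [self.site_labels.index(lab) for lab in labels]
        red = partial_trace(self.matrix, keep, [2] * self.n_sites)
        return DensityOperator(red, [self.site_labels[k] for k in sorted(keep)])


def _maximal_adjacency(n_buffer: int) -> np.ndarray:
    a = np.ones((n_buffer, n_buffer), dtype=np.int64) - np.eye(n_buffer, dtype=np.int64)
    if n_buffer == 5:
        # planar embedding around the central spin forbids the edge between
        # buffers 1 and 5 (1-based buffer-local numbering)
        a[0, 4] = a[4, 0] = 0
    return a


def build_geometry(n_buffer: int, connectivity: str = "maximal",
                   custom_adjacency=None) -> ClusterGeometry:
    """Construct a buffer-network geometry.

    ``connectivity`` is one of ``vanishing`` (no buffer-buffer edges,
    star topology), ``maximal`` (complete buffer graph, minus the 1-5 edge
    when ``n_buffer == 5``; undefined and rejected for ``n_buffer > 5``), or
    ``custom`` (requires ``custom_adjacency``).
    """
    if n_buffer < 2:
        raise ValueError("n_buffer must be at least 2")
    if connectivity == "vanishing":
        if custom_adjacency is not None:
            raise ValueError("custom_adjacency only allowed with connectivity='custom'")
        a = np.zeros((n_buffer, n_buffer), dtype=np.int64)
    elif connectivity == "maximal":
        if custom_adjacency is not None:
            raise ValueError("custom_adjacency only allowed with connectivity='custom'")
        if n_buffer > 5:
            raise ValueError(
                "maximal connectivity is defined only for n_buffer <= 5; "
                "supply a custom adjacency for larger networks"
            )
        a = _maximal_adjacency(n_buffer)
    elif connectivity == "custom":
        if custom_adjacency is None:
            raise ValueError("connectivity='custom' requires custom_adjacency")
        a = np.asarray(custom_adjacency)
    else:
        raise ValueError(f"unknown connectivity {connectivity!r}")
    return ClusterGeometry(n_buffer=n_buffer, buffer_adjacency=a,
                           connectivity_label=connectivity)


def coupling_matrix(geometry: ClusterGeometry, params: ModelParams) -> np.ndarray:
    """Full (N+1)x(N+1) symmetric matrix of pair couplings g_ij.

    Site 0 is the central spin (coupled to every buffer at strength g);
    the buffer block is g times the buffer adjacency.
    """
    n = geometry.n_sites
    gm = np.zeros((n, n))
    gm[0, 1:] = gm[1:, 0] = params.g
    gm[1:, 1:] = params.g * geometry.buffer_adjacency
    return gm


def build_hamiltonian(geometry: ClusterGeometry, params: ModelParams,
                      include_zeeman: bool = True) -> sp.csr_matrix:
    """XX Hamiltonian of one cluster on 2^(N+1) dimensions (sparse).

    ``include_zeeman=False`` drops the uniform sum of (omega/2) sigma_z terms;
    because that sum commutes with the XX coupling and with the thermal
    dissipator, dropping it amounts to working in the frame rotating at omega
    (see :mod:`spinshield.dynamics`).
    """
    n = geometry.n_sites
    dim = 2 ** n
    h = sp.csr_matrix((dim, dim), dtype=complex)
    if include_zeeman:
        for i in range(n):
            h = h + (params.omega / 2.0) * embed(SIGMA_Z, i, n)
    gm = coupling_matrix(geometry, params)
    for i in range(n):
        for j in range(i + 1, n):
            if gm[i, j] != 0.0:
                h = h + gm[i, j] * (
                    embed(SIGMA_X, i, n) @ embed(SIGMA_X, j, n)
                    + embed(SIGMA_Y, i, n) @ embed(SIGMA_Y, j, n)
                )
    return h.tocsr()


def thermal_qubit(params: ModelParams) -> DensityOperator:
    """Single-qubit Gibbs state exp(-beta omega sigma_z / 2) / Z.

    With sigma_z = |0><0| - |1><1| the excited population (on ``|0>``) is
    exp(-beta omega / 2) / (2 cosh(beta omega / 2)); the excited/ground ratio
    is exactly exp(-beta omega).
    """
    if np.isinf(params.beta):
        m = np.diag([0.0, 1.0]).astype(complex)
    else:
        x = params.beta * params.omega / 2.0
        z = 2.0 * np.cosh(x)
        m = np.diag([np.exp(-x) / z, np.exp(x) / z]).astype(complex)
    return DensityOperator(m, ["thermal"])


def bell_state() -> np.ndarray:
    """The shared two-qubit state (|01> + |10>)/sqrt(2) as a density matrix."""
    psi = np.zeros(4, dtype=complex)
    psi[1] = psi[2] = 1.0 / np.sqrt(2.0)
    return np.outer(psi, psi.conj())


def cluster_site_labels(geometry: ClusterGeometry, cluster: str = "A") -> list:
    return [f"{cluster}:central"] + [
        f"{cluster}:buffer{j}" for j in range(1, geometry.n_buffer + 1)
    ]


def initial_cluster_pair_state(geometry: ClusterGeometry,
                               params: ModelParams) -> DensityOperator:
    """Initial state of the two-cluster experiment on 2(N+1) qubits.

    The two central spins carry the Bell state (|01> + |10>)/sqrt(2); all
    2N buffer spins are in the thermal qubit state.  Site order: cluster A
    (central, buffers), then cluster B (central, buffers).
    """
    th = thermal_qubit(params).matrix
    bell = bell_state()  # on (A:central, B:central)
    n = geometry.n_buffer
    # build as bell_(cA,cB) x th^(2N), then permute to (cA, bufA.., cB, bufB..)
    dims = [2] * (2 * n + 2)
    state = bell
    for _ in range(2 * n):
        state = np.kron(state, th)
    # current site order: cA, cB, bufA1..bufAN, bufB1..bufBN
    perm = [0] + list(range(2, 2 + n)) + [1] + list(range(2 + n, 2 + 2 * n))
    state = _permute_sites(state, perm, dims)
    labels = cluster_site_labels(geometry, "A") + cluster_site_labels(geometry, "B")
    return DensityOperator(state, labels)


def _permute_sites(rho: np.ndarray, perm, dims) -> np.ndarray:
    """Reorder tensor factors so that new site k is old site perm[k]."""
    n = len(dims)
    d = int(np.prod(dims))
    t = rho.reshape(dims + list(dims))
    axes = list(perm) + [p + n for p in perm]
    return t.transpose(axes).reshape(d, d)


def plus_minus_states() -> tuple:
    """|+> and |-> on one qubit, as density matrices; orthogonal pure states."""
    plus = np.full((2, 2), 0.5, dtype=complex)
    minus = np.array([[0.5, -0.5], [-0.5, 0.5]], dtype=complex)
    return plus, minus


def adjacency_to_csv(geometry: ClusterGeometry, path) -> None:
    """Write the buffer adjacency matrix as headerless integer CSV."""
    np.savetxt(path, geometry.buffer_adjacency, fmt="%d", delimiter=",")


def adjacency_from_csv(path, connectivity_label: str = "custom") -> ClusterGeometry:
    a = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    return ClusterGeometry(n_buffer=a.shape[0], buffer_adjacency=a,
                           connectivity_label=connectivity_label)
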