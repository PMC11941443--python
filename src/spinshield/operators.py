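"""Low-level qubit operator algebra: Pauli matrices, tensor embedding,
vectorization and partial traces.

Conventions used throughout the package
---------------------------------------
* Computational basis ``|0>``, ``|1>`` with ``sigma_z = |0><0| - |1><1|``,
  i.e. ``|0>`` is the sigma_z = +1 eigenstate (the *excited* state under a
  Hamiltonian ``+ omega/2 sigma_z``) and ``|1>`` is the ground state.
* The lowering operator is ``sigma_minus = |1><0|``.
* Multi-qubit operators are Kronecker products in site order (site 0 is the
  leftmost tensor factor).
* Density matrices are vectorized row-major (C order), so
  ``vec(A rho B) = (A kron B^T) vec(rho)``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SIGMA_X",
    "SIGMA_Y",
    "SIGMA_Z",
    "SIGMA_MINUS",
    "SIGMA_PLUS",
    "IDENTITY_2",
    "embed",
    "kron_all",
    "partial_trace",
    "dagger",
    "vec",
    "unvec",
]

SIGMA_X = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
SIGMA_Y = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
SIGMA_Z = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
#: lowering operator |1><0| in the sigma_z = diag(+1, -1) convention
SIGMA_MINUS = np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex)
SIGMA_PLUS = SIGMA_MINUS.conj().T.copy()
IDENTITY_2 = np.eye(2, dtype=complex)


def dagger(a: np.ndarray) -> np.ndarray:
    return a.conj().T


def kron_all(mats) -> sp.csr_matrix:
    """Sparse Kronecker product of a sequence of matrices, left to right."""
    out = sp.csr_matrix(np.atleast_2d(mats[0]).astype(complex))
    for m in mats[1:]:
        out = sp.kron(out, sp.csr_matrix(np.atleast_2d(m).astype(complex)), format="csr")
    return out


def embed(op: np.ndarray, site: int, n_sites: int) -> sp.csr_matrix:
    """Embed a single-qubit operator at ``site`` in an ``n_sites``-qubit space."""
    if not 0 <= site < n_sites:
        raise ValueError(f"site {site} out of range for {n_sites} qubits")
    mats = [IDENTITY_2] * n_sites
    mats[site] = op
    return kron_all(mats)


def vec(rho: np.ndarray) -> np.ndarray:
    """Row-major vectorization of a square matrix."""
    return np.ascontiguousarray(rho, dtype=complex).reshape(-1)


def unvec(v: np.ndarray) -> np.ndarray:
    d = int(round(np.sqrt(v.size)))
    if d * d != v.size:
        raise ValueError("vector length is not a perfect square")
    return v.reshape(d, d)


def partial_trace(rho: np.ndarray, keep, dims) -> np.ndarray:
    """Partial trace keeping the subsystems listed in ``keep``.

    Parameters
    ----------
    rho : square matrix on the tensor product of subsystems with dimensions
        ``dims`` (site order = tensor order).
    keep : iterable of subsystem indices to retain, in their original order.
    dims : sequence of subsystem dimensions.

    Returns the reduced density matrix on the kept subsystems, ordered as in
    the original tensor product.
    """
    dims = list(dims)
    n = len(dims)
    keep = sorted(set(keep))
    if any(k < 0 or k >= n for k in keep):
        raise ValueError("keep indices out of range")
    d_total = int(np.prod(dims))
    if rho.shape != (d_total, d_total):
        raise ValueError(f"state shape {rho.shape} does not match dims {dims}")
    traced = [i for i in range(n) if i not in keep]
    t = rho.reshape(dims + dims)
    # contract each traced subsystem's row index with its column index
    for offset, i in enumerate(traced):
        ax = i - offset  # axes shift as we trace
        t = np.trace(t, axis1=ax, axis2=ax + (n - offset))
    d_keep = int(np.prod([dims[i] for i in keep])) if keep else 1
    return t.reshape(d_keep, d_keep)
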