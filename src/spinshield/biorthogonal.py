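"""Biorthogonal eigensystems and thermal states of non-Hermitian
effective Hamiltonians.

Effective Hamiltonians of the form ``H_eff = H0 + Delta - (i/2) G`` arise
when a single excitation delocalized over a molecular network couples to the
electromagnetic field (superradiance).  Such matrices are generally
non-Hermitian: their right and left eigenvectors,

    H_eff |E_R> = E |E_R>,    <E_L| H_eff = E <E_L|,

are separately non-orthogonal but jointly biorthogonal,
``<E'_L | E_R> = c_E delta_{E', E}``, giving the spectral decomposition
``H_eff = sum_E E |E_R><E_L| / c_E``.

If the system thermalizes at inverse temperature beta and the spectrum is
real or closed under complex conjugation (with matched degeneracies), the
thermal state is ``rho_th = sum_E e^{-beta E} |E_R><E_L| / (c_E Z)`` with
``Z = sum_E e^{-beta E}``.  Site probabilities ``P(k) = <k| rho_th |k>`` can
then be nonzero on two sites while the off-diagonal element coupling them
vanishes -- so probability maps alone can be misleading evidence of
delocalization; coherence measures (see :mod:`spinshield.metrics`) are the
sharper tool.

Normalization constants ``c_E`` are tracked explicitly rather than absorbed
into the vectors, keeping the spectral decomposition literal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "BiorthogonalSystem",
    "biorthogonal_eigensystem",
    "biorthogonal_thermal_state",
    "site_probabilities",
    "matrix_to_csv",
    "matrix_from_csv",
]

CONDITION_GUARD = 1e12
PAIRING_RTOL = 1e-9


@dataclass
class BiorthogonalSystem:
    """Matched right/left eigenpairs of a diagonalizable matrix.

    ``right_vectors`` and ``left_vectors`` are column-stacked; column j of
    each belongs to ``eigenvalues[j]`` and
    ``left_vectors[:, i].conj() @ right_vectors[:, j] = c_j delta_ij``.
    """

    eigenvalues: np.ndarray
    right_vectors: np.ndarray
    left_vectors: np.ndarray
    normalization: np.ndarray  # c_E

    @property
    def dim(self) -> int:
        return len(self.eigenvalues)

    def reconstruct(self) -> np.ndarray:
        """Rebuild the matrix from sum_E E |E_R><E_L| / c_E."""
        return (self.right_vectors * (self.eigenvalues / self.normalization)) \
            @ self.left_vectors.conj().T

    def completeness_residual(self) -> float:
        ident = (self.right_vectors / self.normalization) @ self.left_vectors.conj().T
        return float(np.abs(ident - np.eye(self.dim)).max())


def biorthogonal_eigensystem(h_eff: np.ndarray,
                             cond_guard: float = CONDITION_GUARD) -> BiorthogonalSystem:
    """Right/left eigendecomposition of a (generally non-Hermitian) matrix.

    Raises for defective or near-defective input (eigenvector matrix
    condition number above ``cond_guard``), the numerical signature of an
    exceptional point where the biorthogonal basis degenerates.
    """
    h = np.asarray(h_eff, dtype=complex)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("h_eff must be a square matrix")
    eigvals, vl, vr = scipy.linalg.eig(h, left=True, right=True)
    cond = np.linalg.cond(vr)
    if not np.isfinite(cond) or cond > cond_guard:
        raise ValueError(
            f"matrix is defective or near-defective (eigenvector condition "
            f"number {cond:.3g}); biorthogonal basis is not reliable"
        )
    # scipy pairs vl/vr column-wise for the same eigenvalue ordering, but
    # within a degenerate eigenspace the pairs need not be biorthogonal;
    # correct the left vectors group by group.
    vl = _biorthogonalize_degenerate(eigvals, vl, vr)
    c = np.einsum("ij,ij->j", vl.conj(), vr)
    if np.abs(c).min() < 1.0 / cond_guard:
        raise ValueError("vanishing biorthogonal norm c_E (exceptional point)")
    return BiorthogonalSystem(eigenvalues=eigvals, right_vectors=vr,
                              left_vectors=vl, normalization=c)


def _degenerate_groups(eigvals: np.ndarray, rtol: float = PAIRING_RTOL):
    scale = max(1.0, np.abs(eigvals).max())
    order = np.lexsort((eigvals.imag, eigvals.real))
    groups, current = [], [order[0]]
    for k in order[1:]:
        if abs(eigvals[k] - eigvals[current[-1]]) <= rtol * scale:
            current.append(k)
        else:
            groups.append(current)
            current = [k]
    groups.append(current)
    return groups


def _biorthogonalize_degenerate(eigvals, vl, vr):
    out = vl.copy()
    for group in _degenerate_groups(eigvals):
        if len(group) < 2:
            continue
        idx = np.array(group)
        m = out[:, idx].conj().T @ vr[:, idx]
        out[:, idx] = out[:, idx] @ np.linalg.inv(m).conj().T
    return out


def _check_conjugate_closed(eigvals: np.ndarray, rtol: float = PAIRING_RTOL):
    """Verify the spectrum is real or closed under conjugation with matched
    degeneracy; raise naming offenders otherwise."""
    scale = max(1.0, np.abs(eigvals).max())
    unmatched = []
    pool = list(eigvals)
    for e in eigvals:
        if abs(e.imag) <= rtol * scale:
            continue
        # find a conjugate partner still in the pool
        best, best_d = None, np.inf
        for k, other in enumerate(pool):
            d = abs(other - np.conj(e))
            if d < best_d:
                best, best_d = k, d
        if best is None or best_d > rtol * scale:
            unmatched.append(e)
    if unmatched:
        raise ValueError(
            "spectrum is neither real nor closed under conjugation; "
            f"unmatched eigenvalues: {unmatched}"
        )


def biorthogonal_thermal_state(h_eff: np.ndarray, beta: float) -> np.ndarray:
    """Thermal state sum_E e^{-beta E} |E_R><E_L| / (c_E Z), unit trace.

    Requires the spectrum to be real or to come in complex-conjugate pairs
    with the same degeneracy; for Hermitian input this reduces to the
    ordinary Gibbs state e^{-beta H}/Z.
    """
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    system = biorthogonal_eigensystem(h_eff)
    _check_conjugate_closed(system.eigenvalues)
    weights = np.exp(-beta * system.eigenvalues)
    z = weights.sum()
    rho = (system.right_vectors * (weights / (system.normalization * z))) \
        @ system.left_vectors.conj().T
    # the conjugation-closed spectrum makes rho real-trace; symmetrize fuzz
    return rho


def site_probabilities(state: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Probability of finding the excitation on each site.

    Accepts either a unit-trace (thermal) matrix -- returning its diagonal --
    or a single (right) eigenvector, returning ``|<k|E_R>|^2`` normalized to
    unit sum.  Output is real, nonnegative within ``tol``, summing to 1.
    """
    arr = np.asarray(state, dtype=complex)
    if arr.ndim == 1 or (arr.ndim == 2 and 1 in arr.shape):
        amp2 = np.abs(arr).ravel() ** 2
        total = amp2.sum()
        if total <= 0:
            raise ValueError("zero vector has no site distribution")
        return amp2 / total
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("state must be a vector or a square matrix")
    p = np.diag(arr)
    if np.abs(p.imag).max() > tol:
        raise ValueError("diagonal has non-negligible imaginary part")
    p = p.real
    if p.min() < -tol:
        raise ValueError(f"negative site probability {p.min():.3g}")
    s = p.sum()
    if abs(s - 1.0) > max(tol, 1e-8):
        raise ValueError(f"probabilities sum to {s:.6g}, not 1 (state not unit trace)")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def matrix_to_csv(matrix: np.ndarray, path) -> None:
    """Write a complex matrix as CSV with alternating real/imag columns."""
    m = np.asarray(matrix, dtype=complex)
    out = np.empty((m.shape[0], 2 * m.shape[1]))
    out[:, 0::2] = m.real
    out[:, 1::2] = m.imag
    np.savetxt(path, out, delimiter=",")


def matrix_from_csv(path) -> np.ndarray:
    raw = np.loadtxt(path, delimiter=",", ndmin=2)
    if raw.shape[1] % 2:
        raise ValueError("expected alternating real/imag column pairs")
    return raw[:, 0::2] + 1j * raw[:, 1::2]
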