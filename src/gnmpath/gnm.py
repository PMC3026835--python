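"""Kirchhoff (connectivity) matrix construction and its spectral quantities.

The contact condition is a closed ball: residues i and j are connected when
their C-alpha distance is <= r_cutoff.  kT and the spring constant gamma are
collapsed into a single multiplicative ``scale`` (default 1); every consumer
in this package uses only relative magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure import CalphaChain

logger = logging.getLogger(__name__)

__all__ = ["GnmModel", "build_kirchhoff", "eigendecompose", "build_model"]

#: eigenvalues below this fraction of the largest one count as zero modes
ZERO_MODE_RTOL = 1e-8


def build_kirchhoff(chain_or_coords, r_cutoff: float) -> np.ndarray:
    """Graph-Laplacian contact matrix: -1 off-diagonal for pairs <= r_cutoff."""
    if r_cutoff <= 0:
        raise ValueError("r_cutoff must be positive")
    coords = (
        chain_or_coords.coords
        if isinstance(chain_or_coords, CalphaChain)
        else np.asarray(chain_or_coords, dtype=float)
    )
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 residues")
    dist = squareform(pdist(coords))
    kirchhoff = -(dist <= r_cutoff).astype(float)
    np.fill_diagonal(kirchhoff, 0.0)
    np.fill_diagonal(kirchhoff, -kirchhoff.sum(axis=1))
    return kirchhoff


@dataclass(frozen=True)
class GnmModel:
    """Eigendecomposed GNM at one cutoff.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the unit eigenvector of
    ``eigenvalues[k]`` with its first non-negligible component positive.
    """

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    gamma: float = 1.0
    r_cutoff: float | None = None
    chain_ref: str | None = None

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @property
    def zero_tol(self) -> float:
        return ZERO_MODE_RTOL * max(self.eigenvalues[-1], 1.0)

    @property
    def n_zero_modes(self) -> int:
        return int(np.sum(self.eigenvalues < self.zero_tol))

    @property
    def is_connected(self) -> bool:
        return self.n_zero_modes == 1

    def nonzero_mode_indices(self) -> np.ndarray:
        return np.arange(self.n_zero_modes, self.n)

    def fastest_mode(self, mode_rank: int = 1):
        """(eigenvalue, eigenvector) of the mode_rank-th largest eigenvalue."""
        n_nonzero = self.n - self.n_zero_modes
        if not 1 <= mode_rank <= n_nonzero:
            raise ValueError(
                f"mode_rank {mode_rank} out of range (1..{n_nonzero} nonzero modes)"
            )
        k = self.n - mode_rank
        return float(self.eigenvalues[k]), self.eigenvectors[:, k]

    def correlation(self, mode_subset=None, scale: float = 1.0) -> np.ndarray:
        """Cross-correlation matrix ``scale * sum_k u_k u_k^T / lambda_k``.

        ``mode_subset`` lists indices into the ascending spectrum; omitted
        means all nonzero modes (the Moore-Penrose pseudo-inverse of the
        Kirchhoff matrix, times scale/gamma).
        """
        if mode_subset is None:
            mode_subset = self.nonzero_mode_indices()
        idx = np.atleast_1d(np.asarray(mode_subset, dtype=int))
        lam = self.eigenvalues[idx]
        if np.any(lam < self.zero_tol):
            raise ValueError("zero mode has no inverse")
        u = self.eigenvectors[:, idx]
        return (scale / self.gamma) * (u / lam) @ u.T

    def distance_fluctuation(self, mode_subset=None, scale: float = 1.0) -> np.ndarray:
        """Mean-square distance fluctuation: C_ii + C_jj - 2 C_ij, zero diagonal."""
        corr = self.correlation(mode_subset, scale=scale)
        diag = np.diag(corr)
        fluct = diag[:, None] + diag[None, :] - 2.0 * corr
        np.fill_diagonal(fluct, 0.0)
        return fluct


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first non-negligible component positive."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        nz = np.nonzero(np.abs(col) > 1e-10 * np.abs(col).max())[0]
        if len(nz) and col[nz[0]] < 0:
            out[:, k] = -col
    return out


def eigendecompose(
    kirchhoff: np.ndarray,
    gamma: float = 1.0,
    r_cutoff: float | None = None,
    chain_ref: str | None = None,
) -> GnmModel:
    """Full spectrum of a symmetric Kirchhoff matrix, ascending order."""
    kirchhoff = np.asarray(kirchhoff, dtype=float)
    if not np.allclose(kirchhoff, kirchhoff.T, atol=1e-10):
        raise ValueError("Kirchhoff matrix must be symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh(kirchhoff)
    eigenvectors = _fix_signs(eigenvectors)
    model = GnmModel(
        kirchhoff=kirchhoff,
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        gamma=gamma,
        r_cutoff=r_cutoff,
        chain_ref=chain_ref,
    )
    if model.n_zero_modes > 1:
        logger.warning(
            "contact graph is disconnected: %d zero modes", model.n_zero_modes
        )
    if model.n >= 2:
        gap = eigenvalues[-1] - eigenvalues[-2]
        if gap < 1e-8 * max(abs(eigenvalues[-1]), 1.0):
            logger.warning("largest eigenvalue is degenerate within 1e-8 relative")
    return model


def build_model(chain: CalphaChain, r_cutoff: float, gamma: float = 1.0) -> GnmModel:
    """Convenience: Kirchhoff + eigendecomposition for one chain and cutoff."""
    kirchhoff = build_kirchhoff(chain, r_cutoff)
    return eigendecompose(
        kirchhoff,
        gamma=gamma,
        r_cutoff=r_cutoff,
        chain_ref=f"{chain.pdb_id}/{chain.chain_id}",
    )
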