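"""Anisotropic network model: Hessian, modes, and cross-correlation maps.

Nodes within the cutoff are joined by identical harmonic springs; the
3N×3N Hessian's low-frequency non-rigid modes give the residue–residue
cross-correlations

    C_ij = cov_ij / sqrt(cov_ii · cov_jj),
    cov_ij = Σ_k (1/λ_k) · v_k[i] · v_k[j]   (3×3 block trace)

which are bounded in [−1, 1] and independent of the spring constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import GeometryError, InvalidSpecificationError

__all__ = ["ANMModel", "CorrelationMap", "build_anm", "cross_correlation",
           "coupling_profile"]

ZERO_MODE_RTOL = 1e-8


@dataclass
class ANMModel:
    coords: np.ndarray           # (N, 3)
    cutoff: float
    gamma: float
    hessian: np.ndarray          # (3N, 3N)
    eigenvalues: np.ndarray      # ascending
    eigenvectors: np.ndarray     # columns
    n_zero_modes: int
    connected: bool

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


@dataclass
class CorrelationMap:
    C: np.ndarray                # (N, N), entries in [−1, 1]
    n_modes: int
    labels: np.ndarray | None = None


def build_anm(coords: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Assemble and diagonalize the ANM super-element Hessian.

    Off-diagonal 3×3 block for a contacting pair (i, j):
    −γ (r_ij ⊗ r_ij) / |r_ij|²; diagonal blocks close the row sums to
    zero.  A connected, non-collinear network has exactly 6 zero modes;
    more triggers a disconnected-network warning and flag.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InvalidSpecificationError(f"coords must be (N, 3), got {coords.shape}")
    n = len(coords)
    if n < 3:
        raise InvalidSpecificationError("need at least 3 nodes")
    centered = coords - coords.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-8:
        raise GeometryError("collinear nodes: ANM is degenerate")

    H = np.zeros((3 * n, 3 * n))
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        d = coords[j] - coords[i]
        block = -gamma * np.outer(d, d) / (d @ d)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    evals, evecs = np.linalg.eigh(H)
    lam_max = float(np.abs(evals).max())
    n_zero = int((np.abs(evals) < ZERO_MODE_RTOL * lam_max).sum())
    connected = n_zero == 6
    if n_zero > 6:
        warnings.warn(
            f"{n_zero} zero modes (> 6): the contact network is disconnected "
            f"at cutoff {cutoff} Å",
            stacklevel=2,
        )
    return ANMModel(coords=coords, cutoff=cutoff, gamma=gamma, hessian=H,
                    eigenvalues=evals, eigenvectors=evecs,
                    n_zero_modes=n_zero, connected=connected)


def cross_correlation(model: ANMModel, n_modes: int = 45) -> CorrelationMap:
    """Normalized residue–residue correlations over the lowest non-zero
    modes (45 by default, a band broad enough to converge the map)."""
    lam_max = float(np.abs(model.eigenvalues).max())
    nonzero = np.flatnonzero(np.abs(model.eigenvalues) >= ZERO_MODE_RTOL * lam_max)
    if n_modes > len(nonzero):
        warnings.warn(
            f"requested {n_modes} modes but only {len(nonzero)} non-zero "
            f"modes exist; truncating",
            stacklevel=2,
        )
        n_modes = len(nonzero)
    sel = nonzero[:n_modes]
    lam = model.eigenvalues[sel]
    V = model.eigenvectors[:, sel]                    # (3N, m)
    W = V / np.sqrt(lam)[None, :]
    n = model.n_nodes
    Wb = W.reshape(n, 3, -1)
    cov = np.einsum("iam,jam->ij", Wb, Wb)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise GeometryError("degenerate node with zero covariance")
    C = cov / np.sqrt(np.outer(diag, diag))
    return CorrelationMap(C=C, n_modes=n_modes)


def coupling_profile(
    entries: list[tuple[int, CorrelationMap, dict[str, np.ndarray]]],
) -> pd.DataFrame:
    """Per-oligomer-size coupling summary.

    Each entry is (size, map, groups) where groups holds node-index arrays
    for "end_lower_N", "end_lower_C", "end_upper_N", "end_upper_C" (for a
    monomer the single subunit is both ends).  Reports the mean |C|
    between the N- and C-domain node sets within each end subunit
    (averaged over the two ends) and between the two end subunits — the
    quantitative handle on how polymerization couples the ends.
    """
    rows = []
    for size, cmap, g in entries:
        C = np.abs(cmap.C)
        within = 0.5 * (
            C[np.ix_(g["end_lower_N"], g["end_lower_C"])].mean()
            + C[np.ix_(g["end_upper_N"], g["end_upper_C"])].mean()
        )
        lower = np.concatenate([g["end_lower_N"], g["end_lower_C"]])
        upper = np.concatenate([g["end_upper_N"], g["end_upper_C"]])
        if size == 1:
            between = np.nan
        else:
            between = C[np.ix_(lower, upper)].mean()
        rows.append({"n_subunits": size,
                     "mean_abs_C_interdomain_ends": float(within),
                     "mean_abs_C_between_ends": float(between)})
    return pd.DataFrame(rows)
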