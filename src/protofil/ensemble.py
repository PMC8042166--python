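"""Conformational-ensemble analysis: distance-matrix SVD, free-energy
landscapes with funnel detection, decorrelation-adjusted regression, and
contact-rearrangement bookkeeping.

The landscape is the negative log of the (optionally smoothed) joint
histogram of the first two principal-component projections, in units of
k_BT, zeroed at the best-sampled bin.  "Funnels" are local minima that
survive a persistence filter: a minimum is counted only if the lowest
saddle connecting it to a deeper minimum lies at least ``barrier`` k_BT
above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import (
    DegeneratePredictorError,
    InsufficientDataError,
    InvalidSpecificationError,
    SelectionError,
)
from .io import Structure, Trajectory

__all__ = [
    "FeatureMatrix",
    "PCProjection",
    "FELGrid",
    "ContactDiff",
    "RegressionResult",
    "distance_features",
    "svd_project",
    "fel",
    "adjusted_regression",
    "contact_map",
    "contact_diff",
]


@dataclass
class FeatureMatrix:
    """Frames × upper-triangular pairwise-distance features (Å)."""

    matrix: np.ndarray           # (F, n(n-1)/2)
    n_atoms: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidSpecificationError("non-finite feature entries")
        expect = self.n_atoms * (self.n_atoms - 1) // 2
        if self.matrix.shape[1] != expect:
            raise InvalidSpecificationError(
                f"feature count {self.matrix.shape[1]} != n(n-1)/2 = {expect}"
            )


def distance_features(traj: Trajectory, selection: np.ndarray) -> FeatureMatrix:
    """Flattened upper triangle of each frame's Cα–Cα distance matrix;
    rigid-motion invariant by construction."""
    sel = np.asarray(selection, dtype=int)
    if sel.size < 2:
        raise SelectionError("need at least 2 selected atoms")
    rows = [pdist(traj.frames[f][sel]) for f in range(traj.n_frames)]
    return FeatureMatrix(matrix=np.asarray(rows), n_atoms=sel.size)


@dataclass
class PCProjection:
    projections: np.ndarray          # (F, k), U·S
    components: np.ndarray           # (k, P) right singular vectors
    singular_values: np.ndarray      # (k,)
    explained_variance: np.ndarray   # (k,) fractions, non-increasing
    column_means: np.ndarray         # (P,)


def svd_project(features: FeatureMatrix, k: int = 2) -> PCProjection:
    """Thin SVD of the column-centered feature matrix.

    Projections are left singular vectors scaled by singular values; each
    component's sign is fixed so its largest-magnitude loading is
    positive.  ``k`` beyond the matrix rank is zero-padded with a warning.
    """
    X = features.matrix
    if X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 frames")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    kk = min(k, len(s))
    if k > rank:
        warnings.warn(
            f"requested {k} components but rank is {rank}; padding with zeros",
            stacklevel=2,
        )
    U, s, Vt = U[:, :kk].copy(), s[:kk].copy(), Vt[:kk].copy()
    s[rank:] = 0.0
    for j in range(kk):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    proj = U * s
    comp = Vt
    if k > kk:                        # pad beyond available singular values
        proj = np.hstack([proj, np.zeros((X.shape[0], k - kk))])
        comp = np.vstack([comp, np.zeros((k - kk, X.shape[1]))])
        s = np.concatenate([s, np.zeros(k - kk)])
    total = (Xc ** 2).sum()
    ev = (s ** 2) / total if total > 0 else np.zeros_like(s)
    return PCProjection(projections=proj, components=comp, singular_values=s,
                        explained_variance=ev, column_means=mu)


@dataclass
class FELGrid:
    """2-D free-energy surface over (PC1, PC2) in k_BT."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray          # (nx, ny); unsampled bins = +inf
    counts: np.ndarray               # raw occupancy
    minima: list[tuple[int, int, float]]   # (ix, iy, persistence in k_BT)

    @property
    def n_minima(self) -> int:
        return len(self.minima)


def _persistent_minima(
    F: np.ndarray,
    occupied: np.ndarray,
    barrier: float,
    counts: np.ndarray,
    min_basin_count: float,
) -> list[tuple[int, int, float]]:
    """Persistence- and occupancy-filtered minima over occupied bins.

    Bins are flooded in order of increasing energy (8-connected); when a
    component first touches a deeper one it dies at that saddle with
    persistence = saddle − its minimum.  A component is a funnel iff its
    persistence reaches ``barrier`` AND the raw frame count accumulated in
    its basin before the merge reaches ``min_basin_count`` — a funnel must
    be both deep and populated, which rejects isolated outlier frames.
    """
    nx, ny = F.shape
    order = sorted(zip(*np.nonzero(occupied)), key=lambda ij: F[ij])
    comp_of: dict[tuple[int, int], int] = {}
    parent: list[int] = []
    comp_min: list[tuple[float, tuple[int, int]]] = []
    persistence: list[float] = []
    basin: list[float] = []          # raw counts accumulated before death

    def find(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for ij in order:
        i, j = ij
        nbr_comps = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                q = (i + di, j + dj)
                if 0 <= q[0] < nx and 0 <= q[1] < ny and q in comp_of:
                    nbr_comps.add(find(comp_of[q]))
        if not nbr_comps:
            c = len(parent)
            parent.append(c)
            comp_min.append((F[ij], ij))
            persistence.append(np.inf)
            basin.append(float(counts[ij]))
            comp_of[ij] = c
            continue
        # attach to the deepest neighbouring component; others die here
        deepest = min(nbr_comps, key=lambda c: comp_min[c][0])
        for c in nbr_comps - {deepest}:
            persistence[c] = F[ij] - comp_min[c][0]
            basin[deepest] += basin[c]
            parent[c] = deepest
        basin[deepest] += float(counts[ij])
        comp_of[ij] = deepest

    out = []
    for c in range(len(parent)):
        if persistence[c] >= barrier and basin[c] >= min_basin_count:
            f_min, ij = comp_min[c]
            out.append((int(ij[0]), int(ij[1]), float(persistence[c])))
    return sorted(out, key=lambda t: F[t[0], t[1]])


def fel(
    projection: PCProjection,
    n_bins: int = 40,
    smooth_sd: float = 1.0,
    barrier: float = 1.0,
    min_basin_fraction: float = 0.02,
) -> FELGrid:
    """Free-energy landscape −ln(P/P_max) over the top-two PC plane.

    ``smooth_sd`` is the Gaussian smoothing width in bins (0 disables);
    ``barrier`` (k_BT) is the watershed persistence threshold for counting
    minima and ``min_basin_fraction`` the fraction of all frames a
    minimum's basin must hold to count as a funnel.
    """
    if n_bins < 2:
        raise InvalidSpecificationError("n_bins must be ≥ 2")
    xy = projection.projections[:, :2]
    counts, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=n_bins)
    P = gaussian_filter(counts, sigma=smooth_sd) if smooth_sd > 0 else counts.copy()
    occupied = P > P.max() * 1e-12
    F = np.full_like(P, np.inf)
    F[occupied] = -np.log(P[occupied] / P.max())
    minima = _persistent_minima(F, occupied, barrier, counts,
                                min_basin_fraction * counts.sum())
    return FELGrid(x_edges=xe, y_edges=ye, free_energy=F, counts=counts,
                   minima=minima)


# ---------------------------------------------------------------------------
# Decorrelation-adjusted regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    F: float
    p_adjusted: float        # nan when n_eff < 4
    n_eff: int
    undersampled: bool


def adjusted_regression(
    x: np.ndarray,
    y: np.ndarray,
    frame_dt: float,
    decorrelation: float = 1.0,
) -> RegressionResult:
    """OLS fit with significance at the decorrelated sample size.

    The slope/intercept/r use every point; the F-test p-value uses an
    effective sample size n_eff = floor(total_time / decorrelation) —
    frames within one decorrelation time (default 1 ns) are not
    independent states.  With decorrelation = frame_dt this reduces to
    the classical F-test.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidSpecificationError("x and y must be equal-length 1-D series")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    n_eff = int(np.floor(len(x) * frame_dt / decorrelation))
    undersampled = n_eff < 4
    if undersampled:
        return RegressionResult(res.slope, res.intercept, r, np.nan, np.nan,
                                n_eff, True)
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        F = np.inf
        p = 0.0
    else:
        F = r2 / (1.0 - r2) * (n_eff - 2)
        p = float(stats.f.sf(F, 1, n_eff - 2))
    return RegressionResult(float(res.slope), float(res.intercept), r,
                            float(F), p, n_eff, False)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _residue_groups(s: Structure, selection: np.ndarray):
    """Selected atoms grouped by residue, in (chain, res_id) order; returns
    ordered residue keys and per-atom ordinal residue indices."""
    sel = np.asarray(selection, dtype=int)
    keys = list(zip(s.chain_id[sel], s.res_id[sel]))
    uniq = sorted(set(keys), key=lambda k: (str(k[0]), int(k[1])))
    pos = {k: i for i, k in enumerate(uniq)}
    ordinals = np.array([pos[k] for k in keys])
    return uniq, ordinals, sel


def contact_map(
    structure: Structure,
    selection: np.ndarray,
    cutoff: float = 4.5,
    min_separation: int = 3,
) -> set[tuple[int, int]]:
    """Residue pairs (ordinal i < j, |i−j| ≥ min_separation) whose minimum
    inter-atom distance is ≤ cutoff."""
    if cutoff <= 0:
        raise InvalidSpecificationError("cutoff must be > 0")
    uniq, ordinals, sel = _residue_groups(structure, selection)
    tree = cKDTree(structure.coords[sel])
    pairs = tree.query_pairs(cutoff)
    out = set()
    for a, b in pairs:
        i, j = int(ordinals[a]), int(ordinals[b])
        if i == j:
            continue
        i, j = min(i, j), max(i, j)
        if j - i >= min_separation:
            out.add((i, j))
    return out


@dataclass
class ContactDiff:
    present_a: set[tuple[int, int]]
    present_b: set[tuple[int, int]]
    gained: set[tuple[int, int]]     # present in B only
    lost: set[tuple[int, int]]       # present in A only
    residues: list                   # ordinal → (chain, res_id)


def contact_diff(
    traj_a: Trajectory,
    traj_b: Trajectory,
    selection: np.ndarray,
    cutoff: float = 4.5,
    persistence: float = 0.7,
) -> ContactDiff:
    """Contacts persisting in ≥ ``persistence`` of frames, per ensemble;
    gained/lost pairs between ensembles A → B."""

    def persistent(traj: Trajectory) -> tuple[set, list]:
        counts: dict[tuple[int, int], int] = {}
        residues = None
        for f in range(traj.n_frames):
            s = traj.frame_structure(f)
            if residues is None:
                residues, _, _ = _residue_groups(s, selection)
            for pair in contact_map(s, selection, cutoff):
                counts[pair] = counts.get(pair, 0) + 1
        keep = {p for p, c in counts.items() if c / traj.n_frames >= persistence}
        return keep, residues

    pa, residues = persistent(traj_a)
    pb, _ = persistent(traj_b)
    return ContactDiff(present_a=pa, present_b=pb,
                       gained=pb - pa, lost=pa - pb, residues=residues)
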