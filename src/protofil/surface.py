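"""Solvent-accessible surface area and buried interface area.

SASA uses Shrake–Rupley sphere-point quadrature: each atom's sphere of
radius r_i + probe carries a deterministic Fibonacci-lattice point set, and
points falling inside any neighbour's probe-inflated sphere are occluded.
The buried area of a two-subunit interface is

    buried = (M1 + M2 − M12) / 2

with M1, M2 the SASA of each subunit in isolation and M12 the SASA of the
complex — half the total area the two surfaces lose on contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidSpecificationError, SelectionError
from .io import FilamentModel, Structure, Trajectory, select

__all__ = [
    "ELEMENT_RADII",
    "SasaParams",
    "SasaRecord",
    "InterfaceSeries",
    "fibonacci_sphere",
    "atom_radii",
    "sasa",
    "buried_sasa",
    "interface_series",
]

# van der Waals radii (Å) for real-atom input; synthetic pseudo-atoms use
# the uniform bead radius instead.
ELEMENT_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}


@dataclass(frozen=True)
class SasaParams:
    """Quadrature/probe configuration; absolute areas depend on all three."""

    probe: float = 1.4              # Å, water probe
    n_points: int = 960             # sphere points per atom
    uniform_radius: float | None = 1.9   # Å; None → element lookup

    def __post_init__(self) -> None:
        if self.n_points < 32:
            raise InvalidSpecificationError("n_points must be ≥ 32")
        if self.probe < 0:
            raise InvalidSpecificationError("probe radius must be ≥ 0")


@dataclass
class SasaRecord:
    per_atom: np.ndarray            # (N,) Å²
    probe: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


@dataclass
class InterfaceSeries:
    """Per-frame buried SASA (Å²) for one named interface."""

    interface: str
    buried: np.ndarray              # (F,) Å², clamped at 0 in reports

    def histogram(self, bin_width: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
        lo = np.floor(self.buried.min() / bin_width) * bin_width
        hi = np.ceil(self.buried.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(self.buried, bins=edges)
        return counts, edges


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (golden-angle
    lattice); reproducible across platforms."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_radii(structure: Structure, params: SasaParams) -> np.ndarray:
    """Per-atom radii: uniform bead radius if configured, else element
    lookup from the atom name's leading letter."""
    if params.uniform_radius is not None:
        return np.full(structure.n_atoms, float(params.uniform_radius))
    radii = np.empty(structure.n_atoms)
    for i, name in enumerate(structure.atom_name):
        elem = next((ch for ch in str(name) if ch.isalpha()), "")
        r = ELEMENT_RADII.get(elem.upper())
        if r is None:
            raise InvalidSpecificationError(
                f"no radius for atom {name!r} (chain {structure.chain_id[i]}, "
                f"residue {structure.res_id[i]})"
            )
        radii[i] = r
    return radii


def _accessible_fractions(
    coords: np.ndarray,
    eff: np.ndarray,
    pts: np.ndarray,
    neighbor_lists: list[np.ndarray],
) -> np.ndarray:
    """Fraction of each atom's sphere points not occluded by its neighbours.

    A point c_i + eff_i·u lies inside neighbour j's sphere iff
    u · d_ij > (eff_i² + |d_ij|² − eff_j²) / (2·eff_i), which turns the
    occlusion test into one matrix product per atom.
    """
    n = len(coords)
    frac = np.ones(n)
    for i in range(n):
        nb = neighbor_lists[i]
        if nb.size == 0:
            continue
        d = coords[nb] - coords[i]                        # (k, 3)
        d2 = (d * d).sum(axis=1)
        thresh = (eff[i] ** 2 + d2 - eff[nb] ** 2) / (2.0 * eff[i])
        occluded = (pts @ d.T > thresh[None, :]).any(axis=1)
        frac[i] = 1.0 - occluded.mean()
    return frac


def _neighbor_lists(
    coords: np.ndarray, eff: np.ndarray, within: np.ndarray | None = None
) -> list[np.ndarray]:
    """Indices of spheres overlapping each atom's probe-inflated sphere;
    ``within`` optionally restricts occluders to a group mask per atom."""
    tree = cKDTree(coords)
    n = len(coords)
    pairs = tree.query_pairs(2.0 * eff.max(), output_type="ndarray")
    adj: list[list[int]] = [[] for _ in range(n)]
    if len(pairs):
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        close = (d * d).sum(axis=1) < (eff[pairs[:, 0]] + eff[pairs[:, 1]]) ** 2
        for i, j in pairs[close]:
            adj[i].append(j)
            adj[j].append(i)
    return [np.array(a, dtype=int) for a in adj]


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaRecord:
    """Shrake–Rupley SASA (Å² per atom) on probe-inflated spheres."""
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(radii <= 0):
        raise InvalidSpecificationError("all radii must be positive")
    if n_points < 32:
        raise InvalidSpecificationError("n_points must be ≥ 32")
    eff = radii + probe
    pts = fibonacci_sphere(n_points)
    frac = _accessible_fractions(coords, eff, pts, _neighbor_lists(coords, eff))
    per_atom = frac * 4.0 * np.pi * eff ** 2
    return SasaRecord(per_atom=per_atom, probe=probe, n_points=n_points)


def structure_sasa(structure: Structure, params: SasaParams = SasaParams()) -> SasaRecord:
    return sasa(structure.coords, atom_radii(structure, params),
                probe=params.probe, n_points=params.n_points)


def _buried_pair(
    coords: np.ndarray,
    eff: np.ndarray,
    group: np.ndarray,
    pts: np.ndarray,
) -> float:
    """(M1 + M2 − M12)/2 computed in one pass: for every atom the
    accessible fraction is evaluated twice, once with occluders restricted
    to the atom's own subunit (the isolated-subunit surface) and once with
    all occluders (the complex surface); the two differ only on interface
    atoms."""
    nb_all = _neighbor_lists(coords, eff)
    nb_own = [nb[group[nb] == group[i]] for i, nb in enumerate(nb_all)]
    frac_all = _accessible_fractions(coords, eff, pts, nb_all)
    frac_own = _accessible_fractions(coords, eff, pts, nb_own)
    areas = 4.0 * np.pi * eff ** 2
    return float(0.5 * ((frac_own - frac_all) * areas).sum())


def buried_sasa(
    structure: Structure,
    model: FilamentModel,
    subunit_a: str,
    subunit_b: str,
    params: SasaParams = SasaParams(),
) -> float:
    """Buried interface area (M1 + M2 − M12)/2 in Å² for two subunits:
    each subunit's SASA in isolation minus its SASA in the complex,
    halved."""
    idx_a = select(structure, model, subunit=subunit_a)
    idx_b = select(structure, model, subunit=subunit_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise SelectionError(f"empty subunit selection {subunit_a!r}/{subunit_b!r}")
    if np.intersect1d(idx_a, idx_b).size:
        raise InvalidSpecificationError("subunit atom sets overlap")
    radii = atom_radii(structure, params)
    both = np.concatenate([idx_a, idx_b])
    group = np.concatenate([np.zeros(idx_a.size, int), np.ones(idx_b.size, int)])
    return _buried_pair(structure.coords[both], radii[both] + params.probe,
                        group, fibonacci_sphere(params.n_points))


def interface_series(
    traj: Trajectory,
    model: FilamentModel,
    interface: str,
    params: SasaParams = SasaParams(),
) -> InterfaceSeries:
    """Per-frame buried SASA for a named interface.

    For the canonical trimer, "bottom" is the bottom–middle pair and
    "top" the middle–top pair.
    """
    pairs = {name: (lo, up) for name, lo, up in model.interfaces}
    if interface not in pairs:
        raise SelectionError(
            f"unknown interface {interface!r}; have {sorted(pairs)}"
        )
    lo, up = pairs[interface]
    buried = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        buried[f] = buried_sasa(traj.frame_structure(f), model, lo, up, params)
    return InterfaceSeries(interface=interface, buried=np.maximum(buried, 0.0))
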