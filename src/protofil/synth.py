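"""Synthetic filament structures and trajectories with known ground truth.

A pseudo-subunit is two rigid point clouds ("N" and "C" domains) on
jittered spherical shells whose centroids sit exactly ``domain_separation``
apart along an axis tilted off the filament z-axis, so that a filament
frame (preferred bending direction) is well defined and consecutive
subunits make shell–shell contact across each interface.  Trajectory
frames are drawn from a small number of conformer clusters, each defined
by an inter-subunit rotation triple (θ1, θ2, θ3), a set of subunits whose
inter-domain distance is reduced (tense → relaxed emulation), and a set of
interfaces rigidly opened along +z; per-frame Gaussian angle noise and
per-atom coordinate jitter are added on top.  All randomness comes from a
counter-based Philox generator keyed by (seed, frame, stage), so outputs
are bitwise-reproducible pure functions of the spec.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecificationError
from .geometry import compose_euler, filament_frame
from .io import FilamentModel, Structure, SubunitDef, Trajectory, write_pdb_trajectory
from .surface import fibonacci_sphere

__all__ = [
    "SubunitTemplate",
    "ClusterSpec",
    "TrajectorySpec",
    "GroundTruthLog",
    "build_filament",
    "generate_trajectory",
    "write_fixture_set",
    "gtp_clusters",
    "gdp_clusters",
]

_STAGE_CLUSTER, _STAGE_ANGLE, _STAGE_JITTER = 0, 1, 2


@dataclass(frozen=True)
class SubunitTemplate:
    """Geometry of one pseudo-subunit (defaults give 54 pseudo-residues)."""

    n_domain_points: int = 30
    c_domain_points: int = 24
    domain_separation: float = 30.0     # Å between domain centroids (T state)
    bead_radius: float = 6.0            # Å, coarse bead ≈ 3 residues
    subunit_rise: float = 40.0          # Å, longitudinal stacking spacing
    domain_radius: float = 11.0         # Å, shell radius of each domain cloud
    domain_axis_tilt: float = 20.0      # deg, N→C axis tilt from +z
    jitter_amplitude: float = 0.6       # Å, deterministic radial shell jitter

    def __post_init__(self) -> None:
        if self.n_domain_points < 4 or self.c_domain_points < 4:
            raise InvalidSpecificationError("domain point counts must be ≥ 4")
        if self.domain_separation <= 0:
            raise InvalidSpecificationError("domain_separation must be > 0")
        if self.bead_radius <= 0 or self.subunit_rise <= 0 or self.domain_radius <= 0:
            raise InvalidSpecificationError("lengths must be positive")

    @property
    def n_points(self) -> int:
        return self.n_domain_points + self.c_domain_points

    def domain_axis(self) -> np.ndarray:
        a = np.radians(self.domain_axis_tilt)
        return np.array([np.sin(a), 0.0, np.cos(a)])


def _domain_cloud(n: int, radius: float, jitter: float, phase: int) -> np.ndarray:
    """Deterministic jittered shell with exactly zero centroid."""
    pts = fibonacci_sphere(n)
    radial = 1.0 + (jitter / radius) * np.sin(7.3 * np.arange(n) + phase)
    cloud = pts * (radius * radial)[:, None]
    return cloud - cloud.mean(axis=0)


def _subunit_labels(n: int) -> list[str]:
    if n == 1:
        return ["bottom"]
    if n == 2:
        return ["bottom", "top"]
    if n == 3:
        return ["bottom", "middle", "top"]
    return ["bottom"] + [f"mid{i}" for i in range(2, n)] + ["top"]


def build_filament(
    template: SubunitTemplate = SubunitTemplate(),
    n_subunits: int = 3,
) -> tuple[Structure, FilamentModel]:
    """Straight filament stacked along +z at ``subunit_rise`` spacing.

    Deterministic given the template.  Returns the structure together with
    the matching filament annotation (chains A, B, C … bottom → top; N
    domain = residues 1..n, C domain = the rest).
    """
    if n_subunits < 1:
        raise InvalidSpecificationError("n_subunits must be ≥ 1")
    u = template.domain_axis()
    half = 0.5 * template.domain_separation
    n_cloud = _domain_cloud(template.n_domain_points, template.domain_radius,
                            template.jitter_amplitude, phase=0)
    c_cloud = _domain_cloud(template.c_domain_points, template.domain_radius,
                            template.jitter_amplitude, phase=3)

    labels = _subunit_labels(n_subunits)
    chains = [chr(ord("A") + k) for k in range(n_subunits)]
    coords, a_name, r_name, r_id, ch_id = [], [], [], [], []
    subunits = []
    n_dom = frozenset(range(1, template.n_domain_points + 1))
    c_dom = frozenset(range(template.n_domain_points + 1, template.n_points + 1))
    for k in range(n_subunits):
        center = np.array([0.0, 0.0, k * template.subunit_rise])
        coords.append(n_cloud + center - half * u)
        coords.append(c_cloud + center + half * u)
        a_name += ["CA"] * template.n_points
        r_name += ["GLY"] * template.n_points
        r_id += list(range(1, template.n_points + 1))
        ch_id += [chains[k]] * template.n_points
        subunits.append(SubunitDef(
            label=labels[k], chain=chains[k],
            residues=(1, template.n_points),
            n_domain=n_dom, c_domain=c_dom,
        ))
    structure = Structure(
        coords=np.vstack(coords),
        atom_name=np.array(a_name),
        res_name=np.array(r_name),
        res_id=np.array(r_id),
        chain_id=np.array(ch_id),
    )
    return structure, FilamentModel(subunits=subunits)


@dataclass(frozen=True)
class ClusterSpec:
    """One conformer cluster: imposed rotations, closures, and openings."""

    label: str
    theta: tuple[float, float, float]          # (θ1, θ2, θ3) degrees
    closure_delta: float = 0.0                 # Å inter-domain reduction
    closure_subunits: tuple[str, ...] = ()     # subunits driven T → R
    interface_gap: float = 0.0                 # Å rigid +z opening
    open_interfaces: tuple[str, ...] = ()      # interface names opened


def gtp_clusters() -> list[ClusterSpec]:
    """Two conformers: one all-closed T-T-T, one open-top T-T-R.

    Twist means are the observed θ1 peaks of the closed (−6.1°) and open
    (−35.7°) interface populations in the GTP-bound ensembles.
    """
    return [
        ClusterSpec(label="closed", theta=(-6.1, 2.8, 0.6)),
        ClusterSpec(label="open-top", theta=(-35.7, 2.8, 0.6),
                    closure_delta=3.0, closure_subunits=("top",),
                    interface_gap=4.0, open_interfaces=("top",)),
    ]


def gdp_clusters() -> list[ClusterSpec]:
    """Three conformers emulating the R-R-R / R-R-T / R-T-R trimers with
    closed-interface (−9.4°) and open-interface (−33.1°, mean −24.7°)
    twist populations."""
    return [
        ClusterSpec(label="closed", theta=(-9.4, 13.7, 3.8),
                    closure_delta=3.0,
                    closure_subunits=("bottom", "middle", "top")),
        ClusterSpec(label="open-both", theta=(-33.1, 13.7, 3.8),
                    closure_delta=3.0, closure_subunits=("bottom", "middle"),
                    interface_gap=4.0, open_interfaces=("bottom", "top")),
        ClusterSpec(label="open-twisted", theta=(-24.7, 13.7, 3.8),
                    closure_delta=3.0, closure_subunits=("bottom", "top"),
                    interface_gap=4.0, open_interfaces=("top",)),
    ]


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for one synthetic trajectory."""

    mode: str = "GTP"                          # GTP | GDP | custom
    n_subunits: int = 3
    n_frames: int = 200
    frame_dt: float = 0.1                      # ns
    clusters: tuple[ClusterSpec, ...] | None = None
    cluster_weights: tuple[float, ...] | None = None
    noise_sd: float = 0.3                      # Å per-atom jitter
    angle_noise_sd: float = 2.0                # deg per imposed angle
    seed: int = 0
    template: SubunitTemplate = field(default_factory=SubunitTemplate)

    def resolved_clusters(self) -> tuple[list[ClusterSpec], np.ndarray]:
        if self.clusters is not None:
            clusters = list(self.clusters)
        elif self.mode.upper() == "GTP":
            clusters = gtp_clusters()
        elif self.mode.upper() == "GDP":
            clusters = gdp_clusters()
        else:
            raise InvalidSpecificationError(
                f"mode {self.mode!r} requires an explicit cluster list"
            )
        if not clusters:
            raise InvalidSpecificationError("empty cluster list")
        if self.cluster_weights is None:
            w = np.full(len(clusters), 1.0 / len(clusters))
        else:
            w = np.asarray(self.cluster_weights, dtype=float)
        if len(w) != len(clusters):
            raise InvalidSpecificationError("one weight per cluster required")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidSpecificationError(f"cluster weights sum to {w.sum()}, not 1")
        return clusters, w

    def validate(self) -> None:
        if self.n_frames < 1:
            raise InvalidSpecificationError("n_frames must be ≥ 1")
        if self.n_subunits < 1:
            raise InvalidSpecificationError("n_subunits must be ≥ 1")
        self.resolved_clusters()

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode, "n_subunits": self.n_subunits,
            "n_frames": self.n_frames, "frame_dt": self.frame_dt,
            "noise_sd": self.noise_sd, "angle_noise_sd": self.angle_noise_sd,
            "seed": self.seed,
            "template": vars(self.template).copy(),
        }
        clusters, w = self.resolved_clusters()
        d["clusters"] = [
            {"label": c.label, "theta": list(c.theta),
             "closure_delta": c.closure_delta,
             "closure_subunits": list(c.closure_subunits),
             "interface_gap": c.interface_gap,
             "open_interfaces": list(c.open_interfaces)}
            for c in clusters
        ]
        d["cluster_weights"] = [float(x) for x in w]
        return d


@dataclass
class GroundTruthLog:
    """Per-frame record of what the generator imposed."""

    cluster_label: list[str]                   # F
    theta_top: np.ndarray                      # (F, 3) deg, noise included
    theta_bottom: np.ndarray                   # (F, 3)
    closure: np.ndarray                        # (F, n_subunits) Å
    state_string: list[str]                    # "T-T-R" ordered bottom→top
    interface_open: np.ndarray                 # (F, n_interfaces) bool
    subunit_labels: list[str]
    interface_labels: list[str]

    @property
    def n_frames(self) -> int:
        return len(self.cluster_label)

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "frame": np.arange(self.n_frames),
            "cluster": self.cluster_label,
            "state": self.state_string,
        }
        for j, name in enumerate(("theta1", "theta2", "theta3")):
            d[f"top_{name}"] = self.theta_top[:, j]
            d[f"bottom_{name}"] = self.theta_bottom[:, j]
        for j, lab in enumerate(self.subunit_labels):
            d[f"closure_{lab}"] = self.closure[:, j]
        for j, lab in enumerate(self.interface_labels):
            d[f"open_{lab}"] = self.interface_open[:, j]
        return pd.DataFrame(d)


def _rng(seed: int, frame: int, stage: int) -> np.random.Generator:
    # counter-based generator keyed by (seed, frame, stage): Philox takes a
    # 128-bit key as two uint64 words
    key = np.array([np.uint64(seed), (np.uint64(frame) << np.uint64(4))
                    | np.uint64(stage)], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def generate_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, GroundTruthLog]:
    """Draw frames from the spec's conformer clusters.

    Per frame: (i) sample a cluster; (ii) rotate the end subunits about
    their own centroids by the cluster's (θ1, θ2, θ3) + angle noise,
    expressed in the middle-subunit filament-frame basis; (iii) translate
    the C-domain of closure subunits toward the N-domain; (iv) open the
    designated interfaces by rigidly translating everything above them
    along +z; (v) add per-atom Gaussian jitter.
    """
    spec.validate()
    clusters, weights = spec.resolved_clusters()
    base, model = build_filament(spec.template, spec.n_subunits)
    labels = model.labels
    iface_names = [name for name, _, _ in model.interfaces]
    n_sub = len(labels)

    sub_idx = {lab: np.flatnonzero(base.chain_id == model.subunit(lab).chain)
               for lab in labels}
    dom_idx = {}
    for lab in labels:
        su = model.subunit(lab)
        mask_n = np.isin(base.res_id, list(su.n_domain))
        dom_idx[lab] = (
            np.flatnonzero((base.chain_id == su.chain) & mask_n),
            np.flatnonzero((base.chain_id == su.chain) & ~mask_n),
        )
    movers = []
    if n_sub >= 2:
        movers = [labels[-1], labels[0]]       # top first, then bottom
    anchor = labels[n_sub // 2]
    B = filament_frame(base, model, anchor=anchor).basis if n_sub >= 2 else np.eye(3)

    F = spec.n_frames
    frames = np.empty((F, base.n_atoms, 3))
    log = GroundTruthLog(
        cluster_label=[], theta_top=np.zeros((F, 3)), theta_bottom=np.zeros((F, 3)),
        closure=np.zeros((F, n_sub)), state_string=[],
        interface_open=np.zeros((F, len(iface_names)), dtype=bool),
        subunit_labels=labels, interface_labels=iface_names,
    )
    for f in range(F):
        k = int(_rng(spec.seed, f, _STAGE_CLUSTER).choice(len(clusters), p=weights))
        cl = clusters[k]
        coords = base.coords.copy()

        noise = _rng(spec.seed, f, _STAGE_ANGLE).normal(
            0.0, spec.angle_noise_sd, size=(len(movers), 3))
        thetas = {}
        for m, lab in enumerate(movers):
            th = np.asarray(cl.theta, dtype=float) + noise[m]
            thetas[lab] = th
            idx = sub_idx[lab]
            cent = coords[idx].mean(axis=0)
            R = B @ compose_euler(th) @ B.T
            coords[idx] = (coords[idx] - cent) @ R.T + cent

        for lab in cl.closure_subunits:
            model.subunit(lab)                 # validate label
            nd, cd = dom_idx[lab]
            axis = coords[nd].mean(axis=0) - coords[cd].mean(axis=0)
            axis /= np.linalg.norm(axis)
            coords[cd] += cl.closure_delta * axis
            log.closure[f, labels.index(lab)] = cl.closure_delta

        for name in cl.open_interfaces:
            if name not in iface_names:
                raise InvalidSpecificationError(f"unknown interface {name!r}")
            j = iface_names.index(name)
            for lab in labels[j + 1:]:
                coords[sub_idx[lab]] += np.array([0.0, 0.0, cl.interface_gap])
            log.interface_open[f, j] = True

        if spec.noise_sd > 0:
            coords = coords + _rng(spec.seed, f, _STAGE_JITTER).normal(
                0.0, spec.noise_sd, size=coords.shape)

        frames[f] = coords
        log.cluster_label.append(cl.label)
        if movers:
            log.theta_top[f] = thetas[movers[0]]
            log.theta_bottom[f] = thetas[movers[-1]]
        log.state_string.append("-".join(
            "R" if lab in cl.closure_subunits else "T" for lab in labels))

    traj = Trajectory(reference=base, frames=frames, frame_dt=spec.frame_dt)
    return traj, log


def write_fixture_set(out_dir: str | Path, specs: list[TrajectorySpec]) -> dict:
    """Write PDB + ground-truth TSV + spec echo per trajectory, plus a
    checksummed manifest (manifest.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, spec in enumerate(specs):
        stem = f"traj_{i:02d}_{spec.mode.lower()}"
        traj, log = generate_trajectory(spec)
        pdb_path = out / f"{stem}.pdb"
        tsv_path = out / f"{stem}_truth.tsv"
        spec_path = out / f"{stem}_spec.yaml"
        write_pdb_trajectory(pdb_path, traj)
        log.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
        spec_path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
        for p in (pdb_path, tsv_path, spec_path):
            entries.append({
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            })
    manifest = {"files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
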