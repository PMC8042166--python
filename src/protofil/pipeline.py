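"""Orchestration: generate fixtures, run the analysis stages, report.

``run_generate`` writes synthetic fixture sets from a RunConfig;
``run_analyze`` runs the requested stages on one trajectory and writes
TSVs plus a machine-readable summary and a reproducible run manifest.
Every stage parameter defaults to the classifier/model constants used
throughout the package (2.5 Å and 1.0 Å reduction bands, 1100/1000 Å²
interface bands, 15 Å ANM cutoff with 45 modes, 1 ns decorrelation).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anm import build_anm, cross_correlation
from .ensemble import distance_features, fel, svd_project
from .errors import ProtofilError
from .geometry import decompose_interface_rotation, interdomain_distance, rmsf
from .io import FilamentModel, Trajectory, read_pdb_trajectory, select
from .states import (
    CLOSED_THRESHOLD,
    OPEN_THRESHOLD,
    R_THRESHOLD,
    T_THRESHOLD,
    angle_peaks_by_interface,
    classify_interface,
    classify_subunit,
    species_census,
    trimer_timeline,
)
from .surface import SasaParams, interface_series
from .synth import SubunitTemplate, TrajectorySpec, build_filament, write_fixture_set

__all__ = ["RunConfig", "run_generate", "run_analyze"]

ALL_STAGES = ("angles", "interfaces", "states", "fel", "anm", "rmsf")


@dataclass
class RunConfig:
    # inputs
    trajectory: str | None = None
    filament_model: str | None = None
    out_dir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    # generation
    mode: str = "GTP"
    n_frames: int = 200
    seed: int = 0
    # classification (Å, Å²)
    r_threshold: float = R_THRESHOLD
    t_threshold: float = T_THRESHOLD
    reference_T: float | None = None      # tense-state inter-domain baseline
    closed_threshold: float = CLOSED_THRESHOLD
    open_threshold: float = OPEN_THRESHOLD
    # surface
    probe: float = 1.4
    sasa_points: int = 960
    uniform_radius: float | None = 6.0     # synthetic bead radius
    # ensemble
    fel_bins: int = 40
    fel_smooth: float = 1.0
    fel_barrier: float = 1.0
    decorrelation_ns: float = 1.0
    # ANM
    anm_cutoff: float = 15.0
    anm_modes: int = 45
    frame_dt: float = 0.1

    def sasa_params(self) -> SasaParams:
        return SasaParams(probe=self.probe, n_points=self.sasa_points,
                          uniform_radius=self.uniform_radius)


def run_generate(config: RunConfig, specs: list[TrajectorySpec] | None = None) -> dict:
    """Write a fixture set (PDB + ground truth + spec echo + manifest)."""
    if specs is None:
        specs = [TrajectorySpec(mode=config.mode, n_frames=config.n_frames,
                                seed=config.seed, frame_dt=config.frame_dt)]
    return write_fixture_set(config.out_dir, specs)


def _load_inputs(config: RunConfig) -> tuple[Trajectory, FilamentModel]:
    if config.trajectory is None:
        raise ProtofilError("config.trajectory is required for analysis")
    traj = read_pdb_trajectory(config.trajectory, frame_dt=config.frame_dt)
    if config.filament_model is not None:
        model = FilamentModel.load(config.filament_model)
    else:
        _, model = build_filament(SubunitTemplate())
    return traj, model


def run_analyze(
    config: RunConfig,
    traj: Trajectory | None = None,
    model: FilamentModel | None = None,
    reference=None,
) -> dict:
    """Run the requested stages; returns the summary dict.

    Outputs land under ``config.out_dir``: one TSV per stage, a
    ``summary.json`` with the headline numbers, and ``manifest.json``
    echoing the configuration.  A stage failure is recorded in the
    manifest and the remaining stages still run.
    """
    if traj is None or model is None:
        traj, model = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    failures: dict[str, str] = {}
    t = traj.times_ns
    end_labels = [model.labels[-1], model.labels[0]] if len(model.labels) > 1 else []
    iface_names = [name for name, _, _ in model.interfaces]

    angle_series = []
    interface_sers = []
    interface_states = []

    def stage_angles():
        nonlocal angle_series
        for which in end_labels:
            s = decompose_interface_rotation(traj, model, which=which,
                                             reference=reference)
            angle_series.append(s)
            pd.DataFrame({
                "frame": np.arange(traj.n_frames), "time_ns": t,
                "theta1_deg": s.theta1, "theta2_deg": s.theta2,
                "theta3_deg": s.theta3, "gimbal": s.gimbal,
                "order": s.order,
            }).to_csv(out / f"angles_{which}.tsv", sep="\t", index=False)
        summary["angle_order"] = "ZXY"

    def stage_interfaces():
        nonlocal interface_sers, interface_states
        params = config.sasa_params()
        for name in iface_names:
            ser = interface_series(traj, model, name, params)
            interface_sers.append(ser)
            st = classify_interface(ser, config.closed_threshold,
                                    config.open_threshold)
            interface_states.append(st)
            pd.DataFrame({
                "frame": np.arange(traj.n_frames), "time_ns": t,
                "buried_A2": ser.buried, "label": st.labels,
            }).to_csv(out / f"interface_{name}.tsv", sep="\t", index=False)

    def stage_states():
        sub_states = []
        for lab in model.labels:
            dist = interdomain_distance(traj, model, lab)
            st = classify_subunit(dist, reference_T=config.reference_T,
                                  r_threshold=config.r_threshold,
                                  t_threshold=config.t_threshold)
            sub_states.append(st)
            pd.DataFrame({
                "frame": np.arange(traj.n_frames), "time_ns": t,
                "interdomain_A": dist.distances,
                "reduction_A": st.reduction, "label": st.labels,
            }).to_csv(out / f"subunit_{lab}.tsv", sep="\t", index=False)
        if interface_states:
            timeline = trimer_timeline(sub_states, interface_states)
            timeline.to_dataframe(config.frame_dt).to_csv(
                out / "timeline.tsv", sep="\t", index=False)
            census = species_census(timeline)
            census.to_dataframe().to_csv(out / "census.tsv", sep="\t", index=False)
            summary["census"] = {pos: dict(c) for pos, c in census.positions.items()}
            summary["first_switch_frame"] = census.first_switch
            summary["trimer_states"] = dict(census.trimer_counts)
            if angle_series:
                peaks = angle_peaks_by_interface(angle_series, interface_states,
                                                 nucleotide_tag=config.mode.upper())
                summary["modal_theta1"] = {
                    cat: (None if p.undersampled else round(p.mode_deg, 2))
                    for cat, p in peaks.items()
                }

    def stage_fel():
        sel = select(traj, model, atom_name="CA")
        if sel.size == 0:
            sel = np.arange(traj.reference.n_atoms)
        feats = distance_features(traj, sel)
        proj = svd_project(feats, k=2)
        grid = fel(proj, n_bins=config.fel_bins, smooth_sd=config.fel_smooth,
                   barrier=config.fel_barrier)
        xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        ii, jj = np.meshgrid(np.arange(config.fel_bins),
                             np.arange(config.fel_bins), indexing="ij")
        pd.DataFrame({
            "pc1_bin": xc[ii.ravel()], "pc2_bin": yc[jj.ravel()],
            "F_kBT": grid.free_energy.ravel(),
            "count": grid.counts.ravel().astype(int),
        }).to_csv(out / "fel.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"pc1_bin": xc[i], "pc2_bin": yc[j], "persistence_kBT": p}
             for i, j, p in grid.minima]
        ).to_csv(out / "fel_minima.tsv", sep="\t", index=False)
        summary["funnel_count"] = grid.n_minima
        summary["explained_variance"] = [round(float(v), 4)
                                         for v in proj.explained_variance]

    def stage_anm():
        sel = select(traj, model, atom_name="CA")
        coords = traj.reference.coords[sel] if sel.size else traj.reference.coords
        anm = build_anm(coords, cutoff=config.anm_cutoff)
        cmap = cross_correlation(anm, n_modes=config.anm_modes)
        np.savetxt(out / "anm_correlation.tsv", cmap.C, delimiter="\t", fmt="%.6f")
        np.savetxt(out / "anm_eigenvalues.tsv", anm.eigenvalues, delimiter="\t")
        summary["anm_zero_modes"] = anm.n_zero_modes
        summary["anm_max_abs_C"] = float(np.abs(cmap.C).max())

    def stage_rmsf():
        sel = select(traj, model, atom_name="CA")
        if sel.size == 0:
            sel = np.arange(traj.reference.n_atoms)
        vals = rmsf(traj, sel)
        pd.DataFrame({
            "atom_index": sel,
            "chain": traj.reference.chain_id[sel],
            "res_id": traj.reference.res_id[sel],
            "rmsf_A": vals,
        }).to_csv(out / "rmsf.tsv", sep="\t", index=False)
        summary["rmsf_mean_A"] = float(vals.mean())

    runners = {"angles": stage_angles, "interfaces": stage_interfaces,
               "states": stage_states, "fel": stage_fel, "anm": stage_anm,
               "rmsf": stage_rmsf}
    for stage in config.stages:
        if stage not in runners:
            raise ProtofilError(f"unknown stage {stage!r}; have {list(runners)}")
        try:
            runners[stage]()
        except Exception as e:           # keep partial outputs, mark failure
            failures[stage] = f"{type(e).__name__}: {e}"

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages_run": list(config.stages),
        "failed_stages": failures,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
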