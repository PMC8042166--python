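#!/usr/bin/env python
"""Rotation angles, buried interfaces, T/R states, and the species census.

For each ensemble from 01: decompose per-frame inter-subunit rotations,
compute buried SASA per interface and classify open/closed (1100/1000 Å²),
classify subunits T/R from inter-domain reductions (2.5 Å), and tally the
dimer-species census.  Per-frame TSVs and a summary land under
results/<mode>/.
"""

import json
from pathlib import Path

from protofil.io import read_pdb_trajectory
from protofil.pipeline import RunConfig, run_analyze
from protofil.synth import SubunitTemplate, build_filament

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    base, model = build_filament(SubunitTemplate())
    for mode, stem in (("GTP", "traj_00_gtp"), ("GDP", "traj_01_gdp")):
        traj = read_pdb_trajectory(ROOT / "fixtures" / f"{stem}.pdb")
        cfg = RunConfig(mode=mode, out_dir=str(ROOT / mode.lower()),
                        reference_T=SubunitTemplate().domain_separation,
                        stages=("angles", "interfaces", "states", "rmsf"))
        summary = run_analyze(cfg, traj=traj, model=model, reference=base)
        print(f"== {mode} ==")
        print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
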