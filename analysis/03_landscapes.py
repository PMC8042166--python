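#!/usr/bin/env python
"""Free-energy landscapes over the top two distance-matrix PCs.

SVD of the flattened Cα–Cα distance matrices, projection on PC1/PC2, and
the −ln P landscape in k_BT with watershed funnel detection.  The GTP
ensemble should resolve two funnels and the GDP ensemble three.
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
                        stages=("fel",))
        summary = run_analyze(cfg, traj=traj, model=model, reference=base)
        print(f"{mode}: funnels = {summary['funnel_count']}, "
              f"PC explained variance = {summary['explained_variance']}")


if __name__ == "__main__":
    main()
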