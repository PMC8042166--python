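#!/usr/bin/env python
"""Generate the two synthetic study ensembles with ground truth.

Writes a GTP-mode trajectory (two conformer clusters: all-closed T-T-T and
open-top T-T-R) and a GDP-mode trajectory (three clusters around relaxed,
opened configurations) as multi-model PDB + ground-truth TSV + spec echo
under results/fixtures/, with a checksummed manifest.
"""

from pathlib import Path

from protofil.synth import TrajectorySpec, write_fixture_set

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
N_FRAMES = 600
SEED = 5


def main() -> None:
    specs = [
        TrajectorySpec(mode="GTP", n_frames=N_FRAMES, seed=SEED),
        TrajectorySpec(mode="GDP", n_frames=N_FRAMES, seed=SEED + 1),
    ]
    manifest = write_fixture_set(OUT, specs)
    print(f"wrote {len(manifest['files'])} files to {OUT}")
    for entry in manifest["files"]:
        print(f"  {entry['path']}  sha256:{entry['sha256'][:12]}…")


if __name__ == "__main__":
    main()
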