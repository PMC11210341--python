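"""Simulate the three-condition force-spectroscopy campaign.

Generates synthetic force-distance curves for each antibody/cell condition
(the two branches described in _common) and writes them as TSV curve files
with JSON manifests under scratch/curves/, plus a campaign index under
results/.  Ground-truth labels go to per-cell truth.json sidecars that the
analysis scripts never read -- they are used only at the very end to judge
parameter recovery.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import (ACQUISITION, ASSOC_DWELLS, ASSOC_VELOCITY, BASE_SEED, CONDITIONS,
                     N_ASSOC, N_OFF, OFF_DWELL, OFF_VELOCITIES, RESULTS, SCRATCH, tag)

from forcekinetics import condition_config, simulate_experiment, write_curveset


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    index = {}
    for i, condition in enumerate(CONDITIONS):
        off_cfg = condition_config(condition, n_curves=N_OFF, seed=BASE_SEED + 2 * i,
                                   **ACQUISITION)
        assoc_cfg = condition_config(condition, n_curves=N_ASSOC, seed=BASE_SEED + 2 * i + 1,
                                     **ACQUISITION)
        sets = simulate_experiment(off_cfg, OFF_VELOCITIES, [OFF_DWELL])
        sets += simulate_experiment(assoc_cfg, [ASSOC_VELOCITY], ASSOC_DWELLS)
        out_dir = SCRATCH / tag(condition)
        manifests = []
        for j, cs in enumerate(sets):
            cell_dir = out_dir / f"cell_{j:02d}"
            write_curveset(cs, cell_dir)
            manifests.append(str(cell_dir / "manifest.json"))
        n = sum(len(cs) for cs in sets)
        index[condition] = manifests
        print(f"{condition}: wrote {n} curves in {len(sets)} cells under {out_dir}")
    (RESULTS / "experiment_index.json").write_text(json.dumps(index, indent=1))
    print(f"campaign index -> {RESULTS / 'experiment_index.json'}")


if __name__ == "__main__":
    main()
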