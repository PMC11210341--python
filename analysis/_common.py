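"""Shared paths and the synthetic campaign design for the analysis scripts.

The campaign mirrors the measurement plan of a cell-SMFS kinetics study,
per antibody/cell condition:

* an off-rate branch: a retraction-velocity sweep at saturating dwell time,
  spreading events over loading rates of roughly 50-5000 pN/s;
* an association branch: a dwell-time sweep at the reference velocity
  (3000 nm/s), sampling the pseudo-first-order binding rise.

Curves are generated at 600 samples over a 1000 nm z-range (the same
~1.7 nm sampling pitch as 2000 samples over 3000 nm) to keep the on-disk
campaign compact; raw curve files live under scratch/, derived tables under
results/.
"""
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "curves"
RESULTS = ROOT / "results"

CONDITIONS = ["VHH-FcK/BT-474", "VHH-FcK/BT-474-TR", "Trastuzumab/BT-474"]

OFF_VELOCITIES = [1000.0, 3000.0, 9000.0]
OFF_DWELL = 0.3
N_OFF = 250
ASSOC_VELOCITY = 3000.0
ASSOC_DWELLS = [0.01, 0.03, 0.06, 0.12, 0.2, 0.4]
N_ASSOC = 400

ACQUISITION = dict(samples_per_curve=600, z_range=1000.0)

BASE_SEED = 20240917


def tag(condition: str) -> str:
    return condition.replace("/", "-")
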