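"""Association kinetics: dwell-curve fits, effective concentration, on-rates.

Per condition: fit the saturating-exponential dwell law to the binding
probability and to the double-bond fraction of the reference-velocity cells,
convert the binding time constant to kon through the hemisphere effective
concentration of the tethered antibody (6 nm linker + 4 nm half antibody),
and report kon_2bonds = 1/tau2.  Writes onrate_<condition>.json.
"""
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import ASSOC_VELOCITY, CONDITIONS, RESULTS, tag

from forcekinetics import (CONDITION_PRESETS, effective_concentration, fit_dwell_curve,
                           on_rate, two_bond_on_rate)


def main() -> None:
    ceff = effective_concentration(6.0, 4.0)
    print(f"effective tethered-antibody concentration: {ceff:.3e} M")
    for condition in CONDITIONS:
        t = tag(condition)
        table = pd.read_csv(RESULTS / f"association_{t}.tsv", sep="\t")
        table = table[table["velocity_nm_per_s"] == ASSOC_VELOCITY]
        dwell = table["measured_dwell_s"].to_numpy()
        n = table["n_curves"].to_numpy()
        bind = fit_dwell_curve(dwell, table["binding_probability"].to_numpy(), n_curves=n)
        kon = on_rate(bind.tau, ceff)
        dbl = two_bond_on_rate(dwell, table["double_fraction"].to_numpy(), n_curves=n)
        truth = CONDITION_PRESETS[condition]
        report = {
            "A": bind.A, "t0_s": bind.t0, "tau_s": bind.tau, "ceff_M": ceff,
            "kon_per_M_s": kon,
            "log10_kon_err": (bind.tau_err / bind.tau / np.log(10)
                              if np.isfinite(bind.tau_err) else None),
            "kon2_per_s": 1.0 / dbl.tau,
            "log10_kon2_err": (dbl.tau_err / dbl.tau / np.log(10)
                               if np.isfinite(dbl.tau_err) else None),
        }
        (RESULTS / f"onrate_{t}.json").write_text(json.dumps(report, indent=1))
        print(f"{condition}: kon = {kon:.3g} 1/(M s) (truth {truth['kon']:.3g}), "
              f"kon_2bonds = {1.0 / dbl.tau:.1f} 1/s (truth {truth['kon2_true']}), "
              f"A = {bind.A:.3f}")


if __name__ == "__main__":
    main()
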