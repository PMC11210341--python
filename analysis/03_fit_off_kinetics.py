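"""Dissociation kinetics: gate single-bond events and fit Bell-Evans by ML.

Per condition: take the final rupture of every single-classified curve,
isolate the single-bond population within each velocity group (two-Gaussian
gate, robust unimodal fallback), and maximise the Bell-Evans likelihood over
(koff, xbeta).  Writes offrate_<condition>.json and a binned
force-vs-loading-rate table for plotting, and prints the estimates next to
the generating truths.
"""
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import CONDITIONS, RESULTS, tag

from forcekinetics import (CONDITION_PRESETS, DegenerateFit, RuptureEvent, fit_bell_ml,
                           fit_bimodal, gate_single_bond, most_probable_force)


def load_final_single_events(t: str) -> pd.DataFrame:
    df = pd.read_csv(RESULTS / f"events_{t}.tsv", sep="\t")
    df = df.loc[df.groupby("curve_id")["position_nm"].idxmax()]
    return df[df["class"] == "single"]


def gate_by_velocity(df: pd.DataFrame) -> list:
    gated = []
    for v, group in df.groupby("velocity_nm_per_s"):
        events = [RuptureEvent(force=r.force_pN, position=r.position_nm,
                               noise_sd=r.noise_sd_pN, loading_rate=r.loading_rate_pN_per_s,
                               detection_floor=r.detection_floor_pN, curve_id=str(r.curve_id))
                  for r in group.itertuples()]
        try:
            gated += gate_single_bond(events, fit_bimodal(events))
        except (DegenerateFit, ValueError):
            forces = np.array([e.force for e in events])
            med = np.median(forces)
            sd = max(1.4826 * np.median(np.abs(forces - med)), 1e-6)
            gated += [e for e in events if med - 2 * sd <= e.force <= med + 2 * sd]
    return gated


def main() -> None:
    for condition in CONDITIONS:
        t = tag(condition)
        df = load_final_single_events(t)
        gated = gate_by_velocity(df)
        fit = fit_bell_ml(gated)
        p = fit.params
        truth = CONDITION_PRESETS[condition]
        report = {
            "koff_per_s": p.koff, "xbeta_nm": p.xbeta, "xbeta_angstrom": p.xbeta_angstrom,
            "log10_koff_err": p.log_koff_err, "log10_xbeta_err": p.log_xbeta_err,
            "n_events": fit.n_events, "warnings": fit.warnings,
        }
        (RESULTS / f"offrate_{t}.json").write_text(json.dumps(report, indent=1))
        print(f"{condition}: koff = {p.koff:.3f} 1/s (truth {truth['koff_true']}), "
              f"xbeta = {p.xbeta_angstrom:.1f} A (truth {10 * truth['xbeta_true']:.1f}), "
              f"{fit.n_events} gated events")
        # binned mean force vs loading rate for a Fig-3d-style overlay
        rates = np.array([e.loading_rate for e in gated])
        forces = np.array([e.force for e in gated])
        bins = np.geomspace(rates.min() * 0.99, rates.max() * 1.01, 7)
        rows = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (rates >= lo) & (rates < hi)
            if sel.sum() < 15:
                continue
            r_mid = float(np.median(rates[sel]))
            rows.append({"loading_rate_pN_per_s": r_mid,
                         "mean_force_pN": float(forces[sel].mean()),
                         "sd_force_pN": float(forces[sel].std(ddof=1)),
                         "n": int(sel.sum()),
                         "bell_mode_pN": most_probable_force(p, r_mid)})
        pd.DataFrame(rows).to_csv(RESULTS / f"force_vs_rate_{t}.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
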