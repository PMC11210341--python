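"""Assemble the final kinetics table and judge parameter recovery.

Merges the off- and on-rate fits of every condition into the summary table
(koff, koff_2bonds, kon, kon_2bonds, KD, xbeta, lifetimes), writes it as
JSON/TSV/markdown under results/, and prints each estimate against the
value the generator was given.
"""
import json
import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import CONDITIONS, RESULTS, tag

from forcekinetics import (BellParameters, CONDITION_PRESETS, OnRateFit, format_table,
                           summarize, two_bond_off_rate)


def main() -> None:
    summaries = []
    for condition in CONDITIONS:
        t = tag(condition)
        off = json.loads((RESULTS / f"offrate_{t}.json").read_text())
        on = json.loads((RESULTS / f"onrate_{t}.json").read_text())
        bell = BellParameters(koff=off["koff_per_s"], xbeta=off["xbeta_nm"],
                              log_koff_err=off["log10_koff_err"],
                              log_xbeta_err=off["log10_xbeta_err"])
        onfit = OnRateFit(A=on["A"], t0=on["t0_s"], tau=on["tau_s"], ceff=on["ceff_M"],
                          kon=on["kon_per_M_s"],
                          log_kon_err=on["log10_kon_err"] or float("nan"),
                          kon2=on["kon2_per_s"],
                          log_kon2_err=on["log10_kon2_err"] or float("nan"))
        summaries.append(summarize(bell, onfit, condition))

    (RESULTS / "summary.json").write_text(
        json.dumps([json.loads(s.to_json()) for s in summaries], indent=1))
    (RESULTS / "summary.tsv").write_text(format_table(summaries, "tsv"))
    (RESULTS / "summary.md").write_text(format_table(summaries, "markdown"))
    print(format_table(summaries, "markdown"))

    print("recovery vs generating truths (log10 deviation / propagated SE):")
    for s in summaries:
        truth = CONDITION_PRESETS[s.condition]
        checks = [
            ("koff", s.koff, truth["koff_true"], s.errors["log10_koff"]),
            ("xbeta", s.xbeta_angstrom, 10 * truth["xbeta_true"], s.errors["log10_xbeta"]),
            ("kon", s.kon, truth["kon"], s.errors["log10_kon"]),
            ("kon2", s.kon2, truth["kon2_true"], s.errors["log10_kon2"]),
            ("koff2", s.koff2, two_bond_off_rate(truth["koff_true"]), s.errors["log10_koff"]),
        ]
        parts = []
        for name, est, tr, se in checks:
            dev = math.log10(est / tr)
            parts.append(f"{name} {dev:+.2f}" + (f" ({dev / se:+.1f} SE)" if se and se == se else ""))
        print(f"  {s.condition}: " + ", ".join(parts))


if __name__ == "__main__":
    main()
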