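"""Per-condition kinetics summaries: the table every condition reduces to.

Six quantities per antibody/cell condition -- koff, koff_2bonds, kon,
kon_2bonds, KD and xbeta -- plus bond lifetimes.  Errors on rates follow the
log convention: the fits are normal on log k, not on k, so uncertainties are
carried as standard errors of log10(k).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .bell import BellParameters
from .off_kinetics import bond_lifetime, two_bond_off_rate
from .on_kinetics import OnRateFit

__all__ = ["KineticsSummary", "dissociation_constant", "summarize", "format_table"]

_KD_MODES = ("single_bond", "two_bond")


def dissociation_constant(koff: float, kon: float, mode: str = "single_bond") -> float:
    """Equilibrium dissociation constant, mol/L.

    ``single_bond``: KD = koff/kon (per-bond equilibrium).  ``two_bond``:
    KD = (koff/1.5)/kon, using the whole-molecule off-rate of the
    uncorrelated two-bond reduction.  Both are always reported in the
    summary; single_bond is the default.
    """
    if not (koff > 0 and kon > 0):
        raise ValueError("koff and kon must be positive")
    if mode not in _KD_MODES:
        raise ValueError(f"mode must be one of {_KD_MODES}, got {mode!r}")
    numerator = koff if mode == "single_bond" else two_bond_off_rate(koff)
    return numerator / kon


@dataclass
class KineticsSummary:
    """All derived kinetic quantities for one condition."""

    condition: str
    koff: float                  # 1/s
    koff2: float                 # 1/s, = koff/1.5 exactly
    kon: float                   # 1/(M*s)
    kon2: float                  # 1/s
    kd: float                    # mol/L (configured mode)
    kd_two_bond: float           # mol/L, (koff/1.5)/kon
    xbeta_angstrom: float
    lifetime_single: float       # s, 1/koff
    lifetime_two_bond: float     # s, 1/koff2
    kd_mode: str = "single_bond"
    errors: dict = field(default_factory=dict)  # log10-scale SEs per rate

    def __post_init__(self) -> None:
        for name in ("koff", "koff2", "kon", "kon2", "kd", "kd_two_bond",
                     "xbeta_angstrom", "lifetime_single", "lifetime_two_bond"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if abs(self.koff2 - self.koff / 1.5) > 1e-12 * self.koff:
            raise ValueError("koff2 must equal koff/1.5 exactly")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "KineticsSummary":
        return cls(**json.loads(text))


def summarize(off: BellParameters, on: OnRateFit, condition: str,
              kd_mode: str = "single_bond") -> KineticsSummary:
    """Assemble the per-condition summary from the off- and on-rate fits.

    Raises ValueError listing the missing piece when either fit is absent.
    """
    missing = [name for name, obj in (("off", off), ("on", on)) if obj is None]
    if missing:
        raise ValueError(f"incomplete summary: missing fit(s) {missing}")
    koff2 = two_bond_off_rate(off.koff)
    return KineticsSummary(
        condition=condition,
        koff=off.koff,
        koff2=koff2,
        kon=on.kon,
        kon2=on.kon2,
        kd=dissociation_constant(off.koff, on.kon, kd_mode),
        kd_two_bond=dissociation_constant(off.koff, on.kon, "two_bond"),
        xbeta_angstrom=off.xbeta_angstrom,
        lifetime_single=bond_lifetime(off.koff),
        lifetime_two_bond=bond_lifetime(koff2),
        kd_mode=kd_mode,
        errors={
            "log10_koff": off.log_koff_err,
            "log10_xbeta": off.log_xbeta_err,
            "log10_kon": on.log_kon_err,
            "log10_kon2": on.log_kon2_err,
        },
    )


_ROWS = [
    ("Koff [s^-1]", "koff", "{:.2e}"),
    ("Koff_2bonds [s^-1]", "koff2", "{:.2e}"),
    ("Kon [M^-1 s^-1]", "kon", "{:.2e}"),
    ("Kon_2bonds [s^-1]", "kon2", "{:.2e}"),
    ("KD [M]", "kd", "{:.2e}"),
    ("Xbeta [Angstrom]", "xbeta_angstrom", "{:.2f}"),
    ("lifetime single bond [s]", "lifetime_single", "{:.2f}"),
    ("lifetime two bonds [s]", "lifetime_two_bond", "{:.2f}"),
]


def format_table(summaries: list[KineticsSummary], fmt: str = "markdown") -> str:
    """Render summaries as a quantity-by-condition table (markdown or TSV)."""
    if fmt not in ("markdown", "tsv"):
        raise ValueError("fmt must be 'markdown' or 'tsv'")
    header = ["quantity"] + [s.condition for s in summaries]
    rows = [[label] + [pattern.format(getattr(s, attr)) for s in summaries]
            for label, attr, pattern in _ROWS]
    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in [header] + rows) + "\n"
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines) + "\n"
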