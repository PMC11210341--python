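"""Bell-Evans single-barrier model of forced bond dissociation.

Under a force ramp F(t) = r*t, a bond whose off-rate grows exponentially with
force, koff(F) = koff * exp(F * xbeta / kBT), ruptures at a random force with
density

    p(F | r) = (koff / r) * exp(b*F) * exp(a * (1 - exp(b*F)))

where b = xbeta/kBT and a = koff*kBT / (r*xbeta).  The survival function is
S(F) = exp(a*(1 - exp(b*F))), which inverts in closed form and gives an exact
inverse-CDF sampler.  The most probable rupture force (mode of p, when
positive) is F* = (kBT/xbeta) * ln(r*xbeta/(koff*kBT)) and rises linearly in
ln r -- the signature of a single sharp barrier probed in the thermally
activated regime.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_PER_NM, KBT_PN_NM

__all__ = [
    "BellParameters",
    "rupture_force_pdf",
    "rupture_force_cdf",
    "sample_rupture_forces",
    "most_probable_force",
]


@dataclass
class BellParameters:
    """Single-barrier dissociation parameters.

    Parameters
    ----------
    koff : float
        Zero-force off-rate, 1/s.
    xbeta : float
        Width of the force-driven dissociation path, nm.
    log_koff_err, log_xbeta_err : float, optional
        Standard errors on log10 of each parameter (table convention: the fit
        is normal on log k, not on k).
    kbt : float, optional
        Thermal energy, pN*nm.  Room temperature by default.
    """

    koff: float
    xbeta: float
    log_koff_err: float = field(default=float("nan"))
    log_xbeta_err: float = field(default=float("nan"))
    kbt: float = KBT_PN_NM

    def __post_init__(self) -> None:
        if not (self.koff > 0):
            raise ValueError(f"koff must be positive, got {self.koff}")
        if not (self.xbeta > 0):
            raise ValueError(f"xbeta must be positive, got {self.xbeta}")
        if not (self.kbt > 0):
            raise ValueError(f"kbt must be positive, got {self.kbt}")

    @property
    def xbeta_angstrom(self) -> float:
        return self.xbeta * ANGSTROM_PER_NM


def _ab(bell: BellParameters, loading_rate: float) -> tuple[float, float]:
    if not (loading_rate > 0):
        raise ValueError(f"loading_rate must be positive, got {loading_rate}")
    b = bell.xbeta / bell.kbt
    a = bell.koff * bell.kbt / (loading_rate * bell.xbeta)
    return a, b


def rupture_force_pdf(force, bell: BellParameters, loading_rate: float):
    """Density of the rupture force under a linear ramp at ``loading_rate``.

    Zero below F = 0 (the bond cannot rupture at negative tension under the
    ramp convention used here).
    """
    a, b = _ab(bell, loading_rate)
    f = np.asarray(force, dtype=float)
    out = np.where(
        f >= 0,
        (bell.koff / loading_rate) * np.exp(b * f + a * (1.0 - np.exp(b * f))),
        0.0,
    )
    return out


def rupture_force_cdf(force, bell: BellParameters, loading_rate: float):
    """CDF of the rupture force: 1 - exp(a*(1 - exp(b*F)))."""
    a, b = _ab(bell, loading_rate)
    f = np.asarray(force, dtype=float)
    return np.where(f >= 0, 1.0 - np.exp(a * (1.0 - np.exp(b * f))), 0.0)


def sample_rupture_forces(
    bell: BellParameters,
    loading_rate: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` i.i.d. rupture forces (pN) by exact inverse-CDF sampling.

    Inversion: with E ~ Exp(1), F = (1/b) * ln(1 + E/a).
    """
    if not (n >= 1):
        raise ValueError(f"n must be >= 1, got {n}")
    a, b = _ab(bell, loading_rate)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = rng.exponential(size=int(n))
    return np.log1p(e / a) / b


def most_probable_force(bell: BellParameters, loading_rate: float) -> float:
    """Analytic mode of the rupture-force density, clipped at zero.

    F* = (kBT/xbeta) * ln(r * xbeta / (koff * kBT)).
    """
    a, _ = _ab(bell, loading_rate)
    return max(0.0, (bell.kbt / bell.xbeta) * float(np.log(1.0 / a)))
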