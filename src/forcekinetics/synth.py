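"""Monte-Carlo generator of AFM force-distance curves with known ground truth.

Emulates dynamic force spectroscopy of a tip-tethered antibody on a living
cell: curves of 2000 samples over a ~3000 nm z-range, cantilever spring
constants around 0.01 N/m, retraction velocities giving loading rates of
~50-5000 pN/s, thermal force noise of a few pN, and single/double bond
ruptures following Bell kinetics.

Mechanics of a bound retract trace: the bond is loaded through a PEG linker
modelled as a worm-like chain in series with a linear membrane spring and
the cantilever, so the force rises in the nonlinear, parabolic-like fashion
characteristic of pulling on a membrane-anchored receptor.  Rupture times
are drawn by integrating the Bell hazard koff*exp(F(t)*xbeta/kBT) along the
actual force trajectory (inverse-transform on the cumulative hazard), which
makes the sampled rupture forces exactly consistent with the Bell-Evans
density at the local loading rate v*dF/dz.  Double bonds follow the
uncorrelated two-state Markov chain (rates 2*koff*exp(s*b*F) then
koff*exp(b*F)); after the first rupture the trace drops to the
single-tether tension at the same piezo position and loading continues.

Bond formation obeys the pseudo-first-order dwell-time law
P(t) = A*(1 - exp(-(t - t0)/tau_on)); the double-bond fraction saturates as
A*f2*(1 - exp(-kon2*(t - t0))).

Ground-truth labels (class, planted rupture forces/positions, instantaneous
loading rates) are stored in the curve's ``truth`` sidecar only -- analysis
code never sees them.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import re

import numpy as np

from .bell import BellParameters, sample_rupture_forces  # noqa: F401  (re-export)
from .constants import KBT_PN_NM
from .curve_io import CurveSet, ForceCurve
from .elasticity import wlc_force
from .markov import (  # noqa: F401  (re-export)
    LOAD_SHARING_FACTORS,
    sample_double_bond_forces,
    sample_double_bond_lifetimes,
)
from .on_kinetics import effective_concentration

__all__ = [
    "SimulationConfig",
    "CONDITION_PRESETS",
    "condition_config",
    "sample_rupture_forces",
    "sample_double_bond_forces",
    "sample_double_bond_lifetimes",
    "simulate_force_curve",
    "simulate_experiment",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters and acquisition settings for one condition.

    Kinetic truths default to the canonical nanobody/HER2-positive-cell
    condition; acquisition defaults mirror a typical cell-SMFS setup
    (0.01 N/m cantilever, 3000 nm z-range, 2000 samples, 3 um/s retract).
    """

    # kinetic truths
    koff_true: float = 0.23          # 1/s
    xbeta_true: float = 1.23         # nm
    kon2_true: float = 17.8          # 1/s, second-bond formation rate
    bind_sat_A: float = 0.13         # saturated binding probability
    lag_t0: float = 0.0              # s
    tau_on: float = 0.0263           # s, characteristic association time
    double_sat_frac: float = 0.5     # saturated double-bond share of A
    load_sharing: str = "shared"     # {'shared', 'full'}
    # mechanics
    kc: float = 10.0                 # cantilever, pN/nm (0.01 N/m)
    linker_contour: float = 6.0      # nm, PEG linker
    linker_persistence: float = 0.38 # nm
    membrane_stiffness: float = 0.35 # pN/nm, linear membrane spring
    force_limit: float = 60.0        # pN, approach force trigger
    noise_sd: float = 3.0            # pN thermal force noise
    # acquisition
    retract_velocity: float = 3000.0 # nm/s
    z_range: float = 3000.0          # nm
    samples_per_curve: int = 2000
    n_curves: int = 1000
    seed: int = 0
    condition: str = "synthetic"
    kbt: float = KBT_PN_NM

    def __post_init__(self) -> None:
        positive = {
            "koff_true": self.koff_true, "xbeta_true": self.xbeta_true,
            "kon2_true": self.kon2_true, "tau_on": self.tau_on, "kc": self.kc,
            "linker_contour": self.linker_contour,
            "linker_persistence": self.linker_persistence,
            "membrane_stiffness": self.membrane_stiffness,
            "force_limit": self.force_limit,
            "retract_velocity": self.retract_velocity, "z_range": self.z_range,
            "kbt": self.kbt,
        }
        for name, value in positive.items():
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not (0.0 <= self.bind_sat_A <= 1.0):
            raise ValueError(f"bind_sat_A must be in [0, 1], got {self.bind_sat_A}")
        if not (0.0 <= self.double_sat_frac <= 1.0):
            raise ValueError(f"double_sat_frac must be in [0, 1], got {self.double_sat_frac}")
        if self.lag_t0 < 0:
            raise ValueError("lag_t0 must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.samples_per_curve < 2:
            raise ValueError("samples_per_curve must be >= 2")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.load_sharing not in LOAD_SHARING_FACTORS:
            raise ValueError(f"load_sharing must be one of {sorted(LOAD_SHARING_FACTORS)}")

    @property
    def bell(self) -> BellParameters:
        return BellParameters(koff=self.koff_true, xbeta=self.xbeta_true, kbt=self.kbt)


#: Kinetic truths for the three study conditions (antibody / cell line),
#: used as canonical fixture parameterisations.  tau_on is derived from the
#: condition's on-rate through the hemisphere effective concentration of a
#: 6 nm linker + 4 nm half-antibody tether.
_CEFF_DEFAULT = effective_concentration(6.0, 4.0)
CONDITION_PRESETS: dict[str, dict] = {
    "VHH-FcK/BT-474": dict(koff_true=0.23, xbeta_true=1.23, kon=4.79e4, kon2_true=17.8),
    "VHH-FcK/BT-474-TR": dict(koff_true=0.77, xbeta_true=1.105, kon=3.60e4, kon2_true=16.7),
    "Trastuzumab/BT-474": dict(koff_true=0.31, xbeta_true=1.401, kon=5.96e4, kon2_true=22.2),
}


def condition_config(name: str, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named condition preset."""
    preset = dict(CONDITION_PRESETS[name])
    kon = preset.pop("kon")
    cfg = SimulationConfig(condition=name, tau_on=1.0 / (kon * _CEFF_DEFAULT), **preset)
    return replace(cfg, **overrides) if overrides else cfg


# --- tether mechanics -------------------------------------------------------

_F_CAP = 2000.0   # pN, upper end of the force grid for the z<->F mapping
_N_MAP = 4000


def _tether_maps(config: SimulationConfig):
    """Piezo position z as a function of total force F for one and two
    parallel tethers (WLC + membrane spring + cantilever in series), plus
    dz/dF for instantaneous-stiffness bookkeeping."""
    f = np.linspace(0.0, _F_CAP, _N_MAP)
    # invert the WLC law once on a fine extension grid
    u = np.linspace(0.0, 1.0 - 1e-6, 8000)
    f_of_u = wlc_force(u * config.linker_contour, config.linker_contour,
                       config.linker_persistence, config.kbt)
    x_wlc = np.interp(f, f_of_u, u * config.linker_contour)
    z1 = x_wlc + f / config.membrane_stiffness + f / config.kc
    # two parallel tethers share the load: each carries F/2 at equal extension
    x_wlc_half = np.interp(f / 2.0, f_of_u, u * config.linker_contour)
    z2 = x_wlc_half + (f / 2.0) / config.membrane_stiffness + f / config.kc
    return f, z1, z2


def _force_on_grid(z: np.ndarray, f_grid: np.ndarray, z_of_f: np.ndarray) -> np.ndarray:
    force = np.interp(z, z_of_f, f_grid, left=0.0)
    return np.where(z > 0, force, 0.0)


def _stiffness_at(force: float, f_grid: np.ndarray, z_of_f: np.ndarray) -> float:
    dz_df = np.gradient(z_of_f, f_grid)
    return 1.0 / float(np.interp(force, f_grid, dz_df))


def _hazard_rupture_index(force: np.ndarray, dt: float, koff: float, s_times_b: float,
                          prefactor: float, threshold: float, start: int) -> int:
    """First index at which the integrated Bell hazard crosses an Exp(1)
    threshold; trapezoidal cumulative hazard on the sampling grid."""
    rate = prefactor * koff * np.exp(s_times_b * np.clip(force, 0.0, None))
    rate[:start] = 0.0
    cum = np.cumsum((rate[:-1] + rate[1:]) * 0.5 * dt)
    idx = int(np.searchsorted(cum, threshold))
    return min(idx + 1, force.size - 1)


# --- curve assembly ---------------------------------------------------------

def _formation_probabilities(config: SimulationConfig, dwell_time: float) -> tuple[float, float]:
    t = dwell_time - config.lag_t0
    if t <= 0:
        return 0.0, 0.0
    p1 = config.bind_sat_A * (1.0 - np.exp(-t / config.tau_on))
    p2 = config.bind_sat_A * config.double_sat_frac * (1.0 - np.exp(-config.kon2_true * t))
    return float(p1), float(min(p2, p1))


def simulate_force_curve(
    config: SimulationConfig,
    dwell_time: float,
    seed: int | np.random.Generator,
    curve_id: str = "sim",
) -> ForceCurve:
    """Simulate one approach/(dwell)/retract cycle.

    The tip-cell contact extent is chosen so that the contact travel on
    approach plus retract reproduces ``dwell_time`` at the configured
    velocity (capped at a quarter of the z-range; any remainder becomes an
    explicit constant-height dwell segment).  Identical config + seed give
    bit-identical output.
    """
    if dwell_time < 0:
        raise ValueError("dwell_time must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v = config.retract_velocity
    n = config.samples_per_curve
    n_app = n // 2
    n_ret = n - n_app

    extent = min(dwell_time * v / 2.0, 0.25 * config.z_range)
    remainder = max(0.0, dwell_time - 2.0 * extent / v)
    z_app = np.linspace(config.z_range, -extent, n_app)
    z_ret = np.linspace(-extent, config.z_range, n_ret)
    dz = (config.z_range + extent) / (n_ret - 1)
    sampling_rate = v / dz
    dt = 1.0 / sampling_rate
    n_dwell = int(round(remainder * sampling_rate)) if remainder > 0 else 0
    n_dwell = min(n_dwell, 10 * n)

    k_contact = config.force_limit / extent if extent > 0 else 0.0
    f_app = np.where(z_app < 0, k_contact * z_app, 0.0)  # compressive = negative
    f_dwell = np.full(n_dwell, -config.force_limit)
    f_ret = np.where(z_ret < 0, k_contact * z_ret, 0.0)

    p1, p2 = _formation_probabilities(config, dwell_time)
    u = rng.uniform()
    n_bonds = 2 if u < p2 else (1 if u < p1 else 0)

    truth: dict = {"bond_class": ["none", "single", "double"][n_bonds],
                   "rupture_forces": [], "rupture_positions": [], "loading_rates": []}

    if n_bonds > 0:
        f_grid, z1, z2 = _tether_maps(config)
        b = config.xbeta_true / config.kbt
        s = LOAD_SHARING_FACTORS[config.load_sharing]
        start = int(np.searchsorted(z_ret, 0.0))
        tether1 = _force_on_grid(z_ret, f_grid, z1)
        if n_bonds == 2:
            tether2 = _force_on_grid(z_ret, f_grid, z2)
            i1 = _hazard_rupture_index(tether2, dt, config.koff_true, s * b,
                                       prefactor=2.0, threshold=rng.exponential(),
                                       start=start)
            f1 = float(tether2[i1])
            truth["rupture_forces"].append(f1)
            truth["rupture_positions"].append(float(z_ret[i1]))
            truth["loading_rates"].append(v * _stiffness_at(f1, f_grid, z2))
            # surviving bond: single-tether tension from the same position on
            single = tether1.copy()
            i2 = _hazard_rupture_index(single, dt, config.koff_true, b,
                                       prefactor=1.0, threshold=rng.exponential(),
                                       start=i1)
            f2 = float(single[i2])
            truth["rupture_forces"].append(f2)
            truth["rupture_positions"].append(float(z_ret[i2]))
            truth["loading_rates"].append(v * _stiffness_at(f2, f_grid, z1))
            bound = np.zeros(n_ret)
            bound[:i1] = tether2[:i1]
            bound[i1:i2] = single[i1:i2]
            f_ret = np.where(z_ret > 0, bound, f_ret)
        else:
            i2 = _hazard_rupture_index(tether1, dt, config.koff_true, b,
                                       prefactor=1.0, threshold=rng.exponential(),
                                       start=start)
            f2 = float(tether1[i2])
            truth["rupture_forces"].append(f2)
            truth["rupture_positions"].append(float(z_ret[i2]))
            truth["loading_rates"].append(v * _stiffness_at(f2, f_grid, z1))
            bound = np.zeros(n_ret)
            bound[:i2] = tether1[:i2]
            f_ret = np.where(z_ret > 0, bound, f_ret)

    z = np.concatenate([z_app, np.full(n_dwell, -extent), z_ret])
    force = np.concatenate([f_app, f_dwell, f_ret])
    if config.noise_sd > 0:
        force = force + rng.normal(0.0, config.noise_sd, size=force.size)
    segment = np.array(["approach"] * n_app + ["dwell"] * n_dwell + ["retract"] * n_ret,
                       dtype=object)
    return ForceCurve(z=z, force=force, segment=segment, kc=config.kc, velocity=v,
                      sampling_rate=sampling_rate, curve_id=curve_id, truth=truth)


def simulate_experiment(
    config: SimulationConfig,
    velocity_grid,
    dwell_grid,
) -> list[CurveSet]:
    """Full-factorial experiment: ``n_curves`` per (velocity, dwell) cell.

    Returns one :class:`CurveSet` per cell.  Deterministic under
    ``config.seed``: per-curve seeds are spawned from a single SeedSequence.
    """
    velocities = list(velocity_grid)
    dwells = list(dwell_grid)
    if not velocities or not dwells:
        raise ValueError("velocity_grid and dwell_grid must be non-empty")
    root = np.random.SeedSequence(config.seed)
    sets = []
    cell_seeds = root.spawn(len(velocities) * len(dwells))
    tag = re.sub(r"[^A-Za-z0-9._-]+", "-", config.condition)
    k = 0
    for v in velocities:
        for d in dwells:
            cfg = replace(config, retract_velocity=float(v))
            rng = np.random.default_rng(cell_seeds[k]); k += 1
            curves = [
                simulate_force_curve(cfg, d, rng, curve_id=f"{tag}_v{v:g}_d{d:g}_{i:05d}")
                for i in range(config.n_curves)
            ]
            sets.append(CurveSet(curves=curves, condition=config.condition, dwell_time_s=float(d)))
    return sets
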