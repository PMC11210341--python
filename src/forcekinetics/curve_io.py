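"""Force-distance curve containers and plain-text I/O.

A :class:`ForceCurve` is one approach/(dwell)/retract cycle of cantilever
force versus piezo position.  Conventions: ``z`` increases away from the
surface (negative z = indentation), positive force is tensile (pulling on
the bond), negative force is compressive (tip pressed into the cell).

File dialect (UTF-8 TSV), chosen over vendor AFM binaries so fixtures stay
portable and diffable::

    # curve_id<TAB>c0001
    # spring_constant_pN_per_nm<TAB>10.0
    # velocity_nm_per_s<TAB>3000.0
    # sampling_hz<TAB>2000.0
    z_nm<TAB>force_pN<TAB>segment
    3000.0<TAB>0.12<TAB>approach
    ...

Segment labels are ``approach``, ``dwell``, ``retract`` and must appear
contiguously in that order.  A :class:`CurveSet` groups curves measured under
one condition (antibody/cell pair) at one nominal dwell time; on disk it is a
JSON manifest listing per-curve file paths.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SEGMENTS",
    "CurveFormatError",
    "ForceCurve",
    "CurveSet",
    "read_curve",
    "write_curve",
    "read_curveset",
    "write_curveset",
    "compute_dwell_time",
]

SEGMENTS = ("approach", "dwell", "retract")

_MANDATORY_KEYS = ("curve_id", "spring_constant_pN_per_nm", "velocity_nm_per_s", "sampling_hz")


class CurveFormatError(ValueError):
    """Raised when a curve file violates the TSV dialect; names the line."""


@dataclass
class ForceCurve:
    """One force-distance cycle with acquisition metadata.

    ``truth`` is an optional sidecar of generator ground-truth labels
    (bond class, planted rupture forces/positions, instantaneous loading
    rates).  It is never written into the curve file itself, so analysis
    code cannot accidentally read it.
    """

    z: np.ndarray            # piezo position, nm
    force: np.ndarray        # force, pN (tensile positive)
    segment: np.ndarray      # per-sample label from SEGMENTS
    kc: float                # cantilever spring constant, pN/nm
    velocity: float          # retraction velocity, nm/s
    sampling_rate: float     # Hz
    curve_id: str = "curve"
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = self.z.size
        if n < 2 or self.force.size != n or self.segment.size != n:
            raise ValueError("z, force and segment must share length >= 2")
        if not (self.kc > 0):
            raise ValueError(f"kc must be positive, got {self.kc}")
        if not (self.velocity > 0):
            raise ValueError(f"velocity must be positive, got {self.velocity}")
        bad = set(self.segment) - set(SEGMENTS)
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")
        # labels must be contiguous blocks in canonical order
        order = [lab for i, lab in enumerate(self.segment) if i == 0 or lab != self.segment[i - 1]]
        expected = [s for s in SEGMENTS if s in set(self.segment)]
        if order != expected:
            raise ValueError(f"segments out of order: {order}")

    def segment_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.segment == name)
        if idx.size == 0:
            raise ValueError(f"curve {self.curve_id!r} has no {name!r} segment")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def has_segment(self, name: str) -> bool:
        return bool(np.any(self.segment == name))


@dataclass
class CurveSet:
    """Curves measured under one condition at one nominal dwell time."""

    curves: list
    condition: str = ""
    dwell_time_s: float = float("nan")

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("CurveSet must contain at least one curve")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# curve_id\t{curve.curve_id}\n")
        fh.write(f"# spring_constant_pN_per_nm\t{float(curve.kc)!r}\n")
        fh.write(f"# velocity_nm_per_s\t{float(curve.velocity)!r}\n")
        fh.write(f"# sampling_hz\t{float(curve.sampling_rate)!r}\n")
        fh.write("z_nm\tforce_pN\tsegment\n")
        for z, f, s in zip(curve.z.tolist(), curve.force.tolist(), curve.segment):
            fh.write(f"{z!r}\t{f!r}\t{s}\n")


def read_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    z, force, seg = [], [], []
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        parts = line[1:].strip().split("\t")
        if len(parts) != 2:
            raise CurveFormatError(f"{path}:{i + 1}: malformed header line {line!r}")
        meta[parts[0]] = parts[1]
    for key in _MANDATORY_KEYS:
        if key not in meta:
            raise CurveFormatError(f"{path}: missing mandatory header key {key!r}")
    if i >= len(lines) or lines[i].split("\t") != ["z_nm", "force_pN", "segment"]:
        raise CurveFormatError(f"{path}:{i + 1}: expected column header 'z_nm\\tforce_pN\\tsegment'")
    for j, line in enumerate(lines[i + 1:], start=i + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CurveFormatError(f"{path}:{j}: expected 3 columns, got {len(parts)}")
        try:
            z.append(float(parts[0]))
            force.append(float(parts[1]))
        except ValueError:
            raise CurveFormatError(f"{path}:{j}: non-numeric value in {line!r}") from None
        if parts[2] not in SEGMENTS:
            raise CurveFormatError(f"{path}:{j}: unknown segment label {parts[2]!r}")
        seg.append(parts[2])
    try:
        return ForceCurve(
            z=np.array(z), force=np.array(force), segment=np.array(seg, dtype=object),
            kc=float(meta["spring_constant_pN_per_nm"]),
            velocity=float(meta["velocity_nm_per_s"]),
            sampling_rate=float(meta["sampling_hz"]),
            curve_id=meta["curve_id"],
        )
    except ValueError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def write_curveset(curveset: CurveSet, directory: str | Path, truth_sidecar: bool = True) -> Path:
    """Write each curve as TSV plus a JSON manifest; returns the manifest path.

    Ground-truth labels, when present, go to a separate ``truth.json`` sidecar.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    truth = {}
    for curve in curveset:
        p = directory / f"{curve.curve_id}.tsv"
        write_curve(curve, p)
        paths.append(p.name)
        if curve.truth is not None:
            truth[curve.curve_id] = curve.truth
    manifest = {
        "condition": curveset.condition,
        "dwell_time_s": curveset.dwell_time_s,
        "curves": paths,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    if truth_sidecar and truth:
        (directory / "truth.json").write_text(json.dumps(truth, indent=1))
    return mpath


def read_curveset(manifest_path: str | Path, load_truth: bool = False) -> CurveSet:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    curves = [read_curve(base / name) for name in manifest["curves"]]
    if load_truth and (base / "truth.json").exists():
        truth = json.loads((base / "truth.json").read_text())
        for c in curves:
            c.truth = truth.get(c.curve_id)
    return CurveSet(curves=curves, condition=manifest.get("condition", ""),
                    dwell_time_s=manifest.get("dwell_time_s", float("nan")))


def _contact_extent(z: np.ndarray, force: np.ndarray, threshold: float) -> float:
    """Contact extent (nm) of one segment: from the zero-force contact point
    to the deepest indentation.  The compressive contact ramp is located on
    a smoothed trace as the contiguous super-threshold region touching the
    deepest point, then the contact point is extrapolated from a straight-
    line fit of the raw ramp (unbiased under noise)."""
    from scipy.ndimage import uniform_filter1d

    width = min(15, max(3, force.size // 10))
    s = uniform_filter1d(force, size=width, mode="nearest")
    smooth_threshold = max(threshold / np.sqrt(width), 0.25 * threshold)
    mask = s < -smooth_threshold
    i_deep = int(np.argmin(z))
    if not mask[i_deep]:
        return 0.0
    # contiguous run of contact samples containing the deepest point
    lo = i_deep
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = i_deep
    while hi < mask.size - 1 and mask[hi + 1]:
        hi += 1
    zc, fc = z[lo:hi + 1], force[lo:hi + 1]
    deep = fc < -threshold  # smoothing smears the run edges; fit raw contact only
    if deep.sum() >= 2:
        zc, fc = zc[deep], fc[deep]
    if zc.size < 2 or np.ptp(zc) == 0:
        return 0.0
    slope, intercept = np.polyfit(zc, fc, 1)
    z0 = -intercept / slope if slope != 0 else float(zc.max())
    zmin = float(z.min())
    return max(0.0, min(float(z0), float(z.max())) - zmin)


def compute_dwell_time(
    curve: ForceCurve,
    contact_extent_nm: float | None = None,
    noise_threshold_factor: float = 2.0,
) -> float:
    """Tip-cell dwell time (s) of one curve.

    The time the tip spends in contact is the contact extent travelled on the
    approach plus on the retract, divided by the scan velocity, plus the
    duration of any explicit constant-height dwell segment.  When
    ``contact_extent_nm`` is omitted the contact region is auto-detected on
    each segment as the span where compressive force exceeds
    ``noise_threshold_factor`` times the baseline noise sd.
    """
    if not (curve.velocity > 0):
        raise ValueError("velocity must be positive")
    if contact_extent_nm is not None:
        if contact_extent_nm < 0:
            raise ValueError("contact_extent_nm must be >= 0")
        extent = 2.0 * contact_extent_nm
    else:
        extent = 0.0
        for name in ("approach", "retract"):
            if not curve.has_segment(name):
                raise ValueError(f"curve {curve.curve_id!r} lacks {name!r} segment")
            sl = curve.segment_slice(name)
            zseg, fseg = curve.z[sl], curve.force[sl]
            # baseline noise from the far-from-surface half of the segment
            far = fseg[zseg > np.median(zseg)]
            sd = 1.4826 * np.median(np.abs(far - np.median(far))) if far.size else 0.0
            extent += _contact_extent(zseg, fseg, noise_threshold_factor * max(sd, 1e-12))
    dwell_extra = 0.0
    if curve.has_segment("dwell"):
        n_dwell = int(np.sum(curve.segment == "dwell"))
        dwell_extra = n_dwell / curve.sampling_rate
    return extent / curve.velocity + dwell_extra
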