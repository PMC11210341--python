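"""Curve container, TSV dialect round-trips, dwell-time computation."""
import numpy as np
import pytest

from forcekinetics import (
    CurveFormatError,
    ForceCurve,
    SimulationConfig,
    compute_dwell_time,
    read_curve,
    read_curveset,
    simulate_force_curve,
    write_curve,
    write_curveset,
)
from forcekinetics.curve_io import CurveSet


def _simple_curve(n=20, with_dwell=False):
    n_app = n // 2
    n_ret = n - n_app
    z = np.concatenate([np.linspace(100, -10, n_app), np.linspace(-10, 100, n_ret)])
    f = np.where(z < 0, 2.0 * z, 0.1)
    seg = ["approach"] * n_app + ["retract"] * n_ret
    if with_dwell:
        z = np.concatenate([z[:n_app], [-10.0] * 4, z[n_app:]])
        f = np.concatenate([f[:n_app], [-20.0] * 4, f[n_app:]])
        seg = seg[:n_app] + ["dwell"] * 4 + seg[n_app:]
    return ForceCurve(z=z, force=f, segment=np.array(seg, dtype=object),
                      kc=10.0, velocity=3000.0, sampling_rate=1000.0, curve_id="t1")


class TestRoundTrip:
    @pytest.mark.parametrize("noisy", [False, True])
    def test_write_read_identity(self, tmp_path, noisy):
        if noisy:
            cfg = SimulationConfig(bind_sat_A=1.0, tau_on=1e-6, seed=0)
            curve = simulate_force_curve(cfg, 0.1, seed=3, curve_id="sim")
        else:
            curve = _simple_curve(with_dwell=True)
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        np.testing.assert_array_equal(back.z, curve.z)
        np.testing.assert_array_equal(back.force, curve.force)
        assert list(back.segment) == list(curve.segment)
        assert (back.kc, back.velocity, back.sampling_rate, back.curve_id) == \
               (curve.kc, curve.velocity, curve.sampling_rate, curve.curve_id)

    def test_full_length_curve_parses(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        curve = simulate_force_curve(cfg, 0.0, seed=1, curve_id="len")
        write_curve(curve, tmp_path / "c.tsv")
        assert read_curve(tmp_path / "c.tsv").z.size == 2000

    def test_curveset_manifest_roundtrip(self, tmp_path):
        cfg = SimulationConfig(bind_sat_A=1.0, tau_on=1e-6, seed=2)
        curves = [simulate_force_curve(cfg, 0.1, seed=i, curve_id=f"c{i}") for i in range(3)]
        cs = CurveSet(curves=curves, condition="test", dwell_time_s=0.1)
        manifest = write_curveset(cs, tmp_path / "set")
        back = read_curveset(manifest, load_truth=True)
        assert len(back) == 3 and back.condition == "test"
        assert back.curves[0].truth is not None  # sidecar reattached on demand
        plain = read_curveset(manifest)
        assert plain.curves[0].truth is None


class TestFormatErrors:
    def test_missing_mandatory_header(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("# curve_id\tx\nz_nm\tforce_pN\tsegment\n0.0\t1.0\tretract\n")
        with pytest.raises(CurveFormatError, match="spring_constant_pN_per_nm"):
            read_curve(path)

    def test_non_numeric_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        curve = _simple_curve()
        write_curve(curve, path)
        lines = path.read_text().splitlines()
        lines[7] = "oops\t1.0\tretract"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(CurveFormatError, match=":8"):
            read_curve(path)

    def test_unknown_segment_label(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_curve(_simple_curve(), path)
        text = path.read_text().replace("retract", "pull")
        path.write_text(text)
        with pytest.raises(CurveFormatError):
            read_curve(path)


class TestCurveValidation:
    def test_segments_must_be_ordered(self):
        z = np.linspace(0, 10, 6)
        with pytest.raises(ValueError, match="order"):
            ForceCurve(z=z, force=z, segment=np.array(["retract"] * 3 + ["approach"] * 3,
                                                      dtype=object),
                       kc=10.0, velocity=1.0, sampling_rate=1.0)

    @pytest.mark.parametrize("field,value", [("kc", 0.0), ("velocity", -1.0)])
    def test_positive_metadata(self, field, value):
        kwargs = dict(z=np.arange(4.0), force=np.arange(4.0),
                      segment=np.array(["retract"] * 4, dtype=object),
                      kc=10.0, velocity=1.0, sampling_rate=1.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            ForceCurve(**kwargs)


class TestDwellTime:
    def test_explicit_contact_extent(self):
        curve = _simple_curve()
        # 150 nm contact on each segment at 3000 nm/s -> 0.1 s
        assert compute_dwell_time(curve, contact_extent_nm=150.0) == pytest.approx(0.1)

    def test_zero_extent_gives_zero(self):
        assert compute_dwell_time(_simple_curve(), contact_extent_nm=0.0) == 0.0

    def test_inverse_proportionality_to_velocity(self):
        slow = _simple_curve()
        fast = ForceCurve(z=slow.z, force=slow.force, segment=slow.segment,
                          kc=slow.kc, velocity=2 * slow.velocity,
                          sampling_rate=slow.sampling_rate)
        d_slow = compute_dwell_time(slow, contact_extent_nm=150.0)
        assert compute_dwell_time(fast, contact_extent_nm=150.0) == pytest.approx(d_slow / 2)

    def test_explicit_dwell_segment_adds_duration(self):
        curve = _simple_curve(with_dwell=True)  # 4 samples at 1000 Hz
        base = compute_dwell_time(curve, contact_extent_nm=0.0)
        assert base == pytest.approx(4 / 1000.0)

    @pytest.mark.parametrize("nominal", [0.02, 0.1, 0.35])
    def test_autodetection_recovers_simulated_dwell(self, nominal):
        cfg = SimulationConfig(seed=9)
        rng = np.random.default_rng(17)
        measured = np.median([
            compute_dwell_time(simulate_force_curve(cfg, nominal, rng)) for _ in range(15)
        ])
        assert measured == pytest.approx(nominal, rel=0.15, abs=0.004)
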