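"""Sweep orchestration: normalization, attenuation, maps, outputs."""

import numpy as np
import pandas as pd
import pytest

from ppgmc import (
    EmptyMapError,
    NormalizationError,
    SweepConfig,
    build_density_map,
    distance_attenuation,
    normalize,
    run_configuration,
    run_sweep,
    write_outputs,
)
from ppgmc.kernel import _rasterize
from ppgmc.runner import TABLE_COLUMNS, _result_row


def synthetic_table(rows):
    base = {c: np.nan for c in TABLE_COLUMNS}
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        if not isinstance(d["branch"], str):
            d["branch"] = ("negative"
                           if (r["theta_s_deg"] < 0 or r["theta_d_deg"] < 0)
                           else "positive")
        out.append(d)
    return pd.DataFrame(out, columns=TABLE_COLUMNS)


class TestNormalize:
    def test_reference_rows_are_unity_and_scaling(self):
        df = synthetic_table([
            dict(wavelength_nm=520, distance_mm=2.0, theta_s_deg=15.0,
                 theta_d_deg=25.0, s_bar=2.0e-4),
            dict(wavelength_nm=520, distance_mm=2.0, theta_s_deg=55.0,
                 theta_d_deg=55.0, s_bar=3.0e-4),
            dict(wavelength_nm=520, distance_mm=2.0, theta_s_deg=-15.0,
                 theta_d_deg=-25.0, s_bar=4.0e-5),
            dict(wavelength_nm=520, distance_mm=2.0, theta_s_deg=-55.0,
                 theta_d_deg=-55.0, s_bar=1.0e-5),
        ])
        out = normalize(df)
        assert out.loc[0, "s_bar_prime"] == 1.0
        assert out.loc[1, "s_bar_prime"] == pytest.approx(1.5)
        assert out.loc[2, "s_bar_prime"] == 1.0
        assert out.loc[3, "s_bar_prime"] == pytest.approx(0.25)

    def test_zero_angles_belong_to_positive_branch(self):
        df = synthetic_table([
            dict(wavelength_nm=940, distance_mm=3.0, theta_s_deg=15.0,
                 theta_d_deg=25.0, s_bar=1.0e-4),
            dict(wavelength_nm=940, distance_mm=3.0, theta_s_deg=0.0,
                 theta_d_deg=0.0, s_bar=5.0e-5),
        ])
        out = normalize(df)
        assert out.loc[out["theta_s_deg"] == 0.0, "s_bar_prime"].iloc[0] \
            == pytest.approx(0.5)

    def test_missing_reference_raises_with_location(self):
        df = synthetic_table([
            dict(wavelength_nm=637, distance_mm=4.0, theta_s_deg=35.0,
                 theta_d_deg=35.0, s_bar=1.0e-4),
        ])
        with pytest.raises(NormalizationError, match="637"):
            normalize(df)


class TestDistanceAttenuation:
    def test_mean_ratio_over_shared_configs(self):
        rows = []
        for d, s in [(2.0, 1.0e-4), (5.0, 1.0e-5)]:
            for ts, td in [(15.0, 25.0), (35.0, 35.0)]:
                rows.append(dict(wavelength_nm=520, distance_mm=d,
                                 theta_s_deg=ts, theta_d_deg=td,
                                 s_bar=s * (1 + 0.1 * ts / 55)))
        df = synthetic_table(rows)
        assert distance_attenuation(df, 520) == pytest.approx(0.1)

    def test_zero_angle_rows_excluded(self):
        df = synthetic_table([
            dict(wavelength_nm=520, distance_mm=2.0, theta_s_deg=0.0,
                 theta_d_deg=0.0, s_bar=1e-4),
            dict(wavelength_nm=520, distance_mm=5.0, theta_s_deg=0.0,
                 theta_d_deg=0.0, s_bar=1e-5),
        ])
        with pytest.raises(ValueError):
            distance_attenuation(df, 520)


def test_zero_detection_flagged_not_silent():
    cfg = SweepConfig(photons_base=400, n_seeds=2, base_seed=1)
    res = run_configuration(940, 5.0, -55.0, -55.0, cfg)
    assert res.n_detected == 0
    assert res.flagged_no_detection
    assert np.isnan(res.dpf)


def test_mirror_reciprocity():
    # reflecting the whole arrangement about x = 0 must be statistically
    # identical (sign-convention smoke test)
    cfg = SweepConfig(photons_base=1_000_000, n_seeds=5, base_seed=5)
    a = run_configuration(520, 2.0, 35.0, 35.0, cfg)
    b = run_configuration(520, 2.0, 35.0, 35.0, cfg, mirror=True)
    tol = 3.0 * np.hypot(a.s_bar_se, b.s_bar_se)
    assert abs(a.s_bar - b.s_bar) <= tol


@pytest.fixture(scope="module")
def small_sweep():
    cfg = SweepConfig(wavelengths=(520,), distances=(2.0,),
                      photons_base=20_000, n_seeds=2, base_seed=3)
    return cfg, run_sweep(cfg, pairs=[(15.0, 25.0), (35.0, 35.0)])


class TestOutputs:
    def test_csv_round_trip(self, small_sweep, tmp_path):
        cfg, table = small_sweep
        paths = write_outputs(table, tmp_path, sweep=cfg)
        back = pd.read_csv(paths["sweep_table"], float_precision="round_trip")
        # integral floats come back as ints; values must be exact
        pd.testing.assert_frame_equal(back, table, check_exact=True,
                                      check_dtype=False)

    def test_metadata_contains_config(self, small_sweep, tmp_path):
        import json

        cfg, table = small_sweep
        paths = write_outputs(table, tmp_path, sweep=cfg)
        meta = json.loads(open(paths["run_metadata"]).read())
        for key in ("wavelengths", "distances", "photons_base", "n_seeds",
                    "base_seed", "phase_backend", "acceptance_half_angle"):
            assert key in meta["sweep_config"]

    def test_rerun_reproduces_identical_csv(self, small_sweep, tmp_path):
        cfg, table = small_sweep
        again = run_sweep(cfg, pairs=[(15.0, 25.0), (35.0, 35.0)])
        p1 = tmp_path / "a"
        p2 = tmp_path / "b"
        write_outputs(table, p1, sweep=cfg)
        write_outputs(again, p2, sweep=cfg)
        assert (p1 / "sweep_table.csv").read_bytes() == \
            (p2 / "sweep_table.csv").read_bytes()


class TestDensityMap:
    def test_rasterize_vertical_path_single_column(self):
        grid = np.zeros((50, 40))
        px = np.array([0.55, 0.55])
        pz = np.array([0.0, 3.0])
        pw = np.array([0.8, 0.8])
        _rasterize(px, pz, pw, 2, grid, -2.0, 0.0, 0.1)
        cols = np.nonzero(grid.sum(axis=0))[0]
        assert len(cols) == 1
        assert grid.sum() == pytest.approx(0.8 * 3.0, rel=1e-9)

    def test_map_normalisation_and_depth_trend(self):
        cfg = SweepConfig(photons_base=300_000, n_seeds=2, base_seed=2)
        m2 = build_density_map(520, 2.0, 15.0, 25.0, cfg)
        m5 = build_density_map(520, 5.0, 15.0, 25.0, cfg)
        assert m2.normalized.max() == pytest.approx(1.0)
        # deeper banana at larger source-detector distance
        assert m5.weighted_mean_depth() > m2.weighted_mean_depth()
        # cross-map normalisation against a designated reference
        m5.reference_max = float(m2.grid.max())
        assert m5.normalized.max() != pytest.approx(1.0)

    def test_empty_map_raises(self):
        cfg = SweepConfig(photons_base=400, n_seeds=2, base_seed=1)
        with pytest.raises(EmptyMapError):
            build_density_map(940, 5.0, -55.0, -55.0, cfg)


def test_result_row_has_all_columns():
    cfg = SweepConfig(photons_base=10_000, n_seeds=2, base_seed=1)
    res = run_configuration(520, 2.0, 15.0, 25.0, cfg)
    row = _result_row(res)
    assert list(row) == TABLE_COLUMNS
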