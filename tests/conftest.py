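"""Shared fixtures.

The trend/attenuation tests share one reduced sweep (session scope) so
the expensive Monte Carlo runs happen once.  Test-scale photon budgets
are smaller than the study-scale defaults used by scripts/acceptance.py;
statistical assertions use seed-spread standard errors.
"""

import pytest

from ppgmc import SceneConfig, SweepConfig, build_scene, run_sweep

# reduced diagonal grid used for quick distance-attenuation estimates
REDUCED_PAIRS = [(15.0, 25.0), (35.0, 35.0), (55.0, 55.0)]

# angle pairs exercised by the trend suite (positive grid, zero, negative
# diagonal)
TREND_PAIRS = REDUCED_PAIRS + [
    (15.0, 35.0),
    (15.0, 55.0),
    (35.0, 25.0),
    (55.0, 25.0),
    (0.0, 0.0),
    (-15.0, -25.0),
    (-35.0, -35.0),
    (-55.0, -55.0),
]


@pytest.fixture(scope="session")
def scene_520():
    return build_scene(SceneConfig(), 520)


@pytest.fixture(scope="session")
def scene_940():
    return build_scene(SceneConfig(), 940)


@pytest.fixture(scope="session")
def trend_sweep_config():
    return SweepConfig(
        distances=(2.0, 5.0),
        photons_base=400_000,
        n_seeds=5,
        base_seed=7,
    )


@pytest.fixture(scope="session")
def trend_table(trend_sweep_config):
    """Reduced-grid sweep shared by the trend and attenuation tests."""
    return run_sweep(trend_sweep_config, pairs=TREND_PAIRS)


@pytest.fixture(scope="session")
def negative_table_940():
    """Higher-budget negative-angle diagonal at 940 nm, d = 5 mm.

    Negative-angle DC levels are 10-100x below the positive branch, so the
    depth/DPF trends toward (-55, -55) need a larger photon budget to
    register any detections at all.
    """
    cfg = SweepConfig(
        wavelengths=(940,),
        distances=(5.0,),
        photons_base=3_000_000,
        n_seeds=5,
        base_seed=7,
    )
    pairs = [(-15.0, -25.0), (-35.0, -35.0), (-55.0, -55.0)]
    return run_sweep(cfg, pairs=pairs)


def row(df, wl, d, ts, td):
    sel = df[
        (df["wavelength_nm"] == wl)
        & (df["distance_mm"] == d)
        & (df["theta_s_deg"] == ts)
        & (df["theta_d_deg"] == td)
    ]
    assert len(sel) == 1, f"expected one row for {(wl, d, ts, td)}"
    return sel.iloc[0]


@pytest.fixture(scope="session")
def get_row():
    return row
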