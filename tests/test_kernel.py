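"""Transport kernel physics: Fresnel, Beer, roulette, conservation."""

import math

import numpy as np
import pytest

from ppgmc import (
    KernelConfig,
    OpticalProperties,
    SceneConfig,
    build_scene,
    fresnel_reflectance,
    interface_event,
    run_batch,
    russian_roulette,
    trace,
)
from ppgmc.kernel import KernelInvariantError, PhotonState
from ppgmc.optics import source_detector_pair
from ppgmc.scene import Material, PHANTOM


def absorber_scene(mu_a=0.093, n=1.561, height=5.0):
    """Non-scattering phantom slab: transport reduces to Lambert-Beer."""
    scene = build_scene(SceneConfig(phantom_height=height), 520)
    scene.materials[PHANTOM] = Material(
        "phantom",
        OpticalProperties(mu_a=mu_a, mu_s_reduced=0.0, g=0.0, n=n),
        scattering=False,
    )
    return scene


class TestFresnel:
    def test_index_matched(self):
        assert fresnel_reflectance(1.0, 1.0, 0.7) == 0.0

    def test_normal_incidence_phantom(self):
        expected = ((1.561 - 1.0) / (1.561 + 1.0)) ** 2
        assert fresnel_reflectance(1.0, 1.561, 1.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert fresnel_reflectance(1.0, 1.561, 1.0) == pytest.approx(
            0.0480, abs=1e-4
        )

    def test_total_internal_reflection(self):
        # critical angle from the phantom is asin(1/1.561) ~ 39.9 deg
        ci = math.cos(math.radians(60.0))
        assert fresnel_reflectance(1.561, 1.0, ci) == 1.0

    def test_symmetric_in_direction_of_travel(self):
        # R(n1->n2) = R(n2->n1) at matched transmitted/incident angles
        th1 = math.radians(20.0)
        th2 = math.asin(1.0 * math.sin(th1) / 1.561)
        r12 = fresnel_reflectance(1.0, 1.561, math.cos(th1))
        r21 = fresnel_reflectance(1.561, 1.0, math.cos(th2))
        assert r12 == pytest.approx(r21, abs=1e-12)


class TestInterfaceEvent:
    def test_index_matched_direction_unchanged(self):
        d, reflected = interface_event((0, 0, 1), (0, 0, 1), 1.5, 1.5, u=0.99)
        assert not reflected
        assert np.allclose(d, (0, 0, 1))

    def test_snell_refraction_45deg(self):
        th = math.radians(45.0)
        d_in = (math.sin(th), 0.0, math.cos(th))
        d_out, reflected = interface_event(d_in, (0, 0, 1), 1.0, 1.561, u=0.99)
        assert not reflected
        angle = math.degrees(math.asin(np.hypot(d_out[0], d_out[1])))
        expected = math.degrees(math.asin(math.sin(th) / 1.561))
        assert angle == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(26.93, abs=0.05)

    def test_beyond_critical_always_reflects(self):
        th = math.radians(60.0)
        d_in = (math.sin(th), 0.0, math.cos(th))
        for u in (0.0, 0.5, 0.999999):
            d_out, reflected = interface_event(d_in, (0, 0, 1), 1.561, 1.0, u=u)
            assert reflected
            assert d_out[2] == pytest.approx(-d_in[2])

    def test_unit_norm_preserved(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            v = rng.normal(size=3)
            v[2] = abs(v[2]) + 0.1
            d_out, _ = interface_event(v, (0, 0, 1), 1.0, 1.561,
                                       u=rng.random())
            assert np.linalg.norm(d_out) == pytest.approx(1.0, abs=1e-9)


class TestRussianRoulette:
    def test_above_threshold_untouched(self):
        assert russian_roulette(0.5, u=0.0) == (0.5, True)

    def test_survivor_weight(self):
        w, alive = russian_roulette(1e-5, u=0.05, survival_factor=10.0)
        assert alive and w == pytest.approx(1e-4)

    def test_ensemble_weight_conserved(self):
        # expectation of the post-roulette weight equals the input weight
        rng = np.random.default_rng(11)
        w0 = 1e-5
        n = 1_000_000
        out = np.where(rng.random(n) * 10.0 < 1.0, w0 * 10.0, 0.0)
        assert out.mean() == pytest.approx(w0, rel=5e-3)


class TestBeerLambertLimits:
    def test_nonscattering_phantom_dpf_is_one(self):
        # straight chord through a 5 mm absorber slab: l = t, w = exp(-mu_a t)
        scene = absorber_scene(mu_a=0.093, height=5.0)
        ev = trace((3.0, 0.0, 0.0), (0, 0, 1), scene, seed=1)
        assert ev.kind == "side_exit"  # leaves through the bottom
        assert ev.path_length == pytest.approx(5.0, abs=1e-9)
        assert ev.max_depth == pytest.approx(5.0, abs=1e-9)
        assert ev.weight == pytest.approx(math.exp(-0.093 * 5.0), abs=1e-3)
        dpf = ev.path_length / 5.0
        assert dpf == pytest.approx(1.0, abs=1e-3)

    def test_oblique_chord(self):
        scene = absorber_scene(mu_a=0.05, height=5.0)
        th = math.radians(30.0)
        d = (math.sin(th), 0.0, math.cos(th))
        ev = trace((0.0, 0.0, 0.0), d, scene, seed=1)
        chord = 5.0 / math.cos(th)
        assert ev.path_length == pytest.approx(chord, abs=1e-9)
        assert ev.weight == pytest.approx(math.exp(-0.05 * chord), rel=1e-9)

    def test_glass_transmission_940(self):
        # photons leaving the phantom straight up cross 1 mm of glass:
        # single-pass escapees carry exactly exp(-0.029) = 0.97142
        scene = build_scene(SceneConfig(), 940)
        scene.materials[PHANTOM] = Material(
            "phantom",
            OpticalProperties(mu_a=0.0, mu_s_reduced=0.0, g=0.0, n=1.543),
            scattering=False,
        )
        weights = []
        for seed in range(400):
            ev = trace((5.0, 0.0, 1.0), (0, 0, -1), scene, seed=seed)
            if ev.kind == "escaped":
                weights.append(ev.weight)
        assert weights, "no photon escaped upward"
        assert max(weights) == pytest.approx(math.exp(-0.029), abs=1e-9)
        assert math.exp(-0.029) == pytest.approx(0.97142, abs=1e-5)


@pytest.fixture(scope="module")
def scene():
    return build_scene(SceneConfig(), 520)


class TestTraceBookkeeping:
    def test_terminal_event_exclusive_and_exit_record(self, scene):
        kinds = set()
        for seed in range(300):
            ev = trace((0.5, 0.0, 0.0), (0, 0, 1), scene, seed=seed)
            kinds.add(ev.kind)
            if ev.kind == "escaped":
                assert ev.exit_position is not None
                ex, ey = ev.exit_position
                chord = math.hypot(ex - 0.5, ey)
                assert ev.path_length >= chord - 1e-9
                assert np.linalg.norm(ev.exit_direction) == pytest.approx(
                    1.0, abs=1e-9
                )
                assert ev.exit_direction[2] < 0.0
            assert ev.max_depth <= scene.config.phantom_height
        assert "escaped" in kinds

    def test_barrier_absorbs(self, scene):
        # photon aimed through the barrier from inside the superstructure
        ev = trace((-1.0, 0.0, -0.5), (1, 0, 0), scene, seed=0)
        assert ev.kind == "absorbed"
        assert ev.deposited == pytest.approx(1.0)

    def test_upward_in_ambient_escapes(self, scene):
        ev = trace((10.0, 0.0, -8.0), (0, 0, -1), scene, seed=0)
        assert ev.kind == "escaped"
        assert ev.path_length == 0.0

    def test_nonfinite_state_rejected(self, scene):
        with pytest.raises(KernelInvariantError):
            trace((np.nan, 0, 0), (0, 0, 1), scene)
        with pytest.raises(KernelInvariantError):
            PhotonState(position=(0, 0, 0), direction=(0, 0, 0))


def test_spin_azimuth_uniform_and_independent():
    # azimuth about the incoming axis is uniform on [0, 2pi) regardless of
    # the polar deflection: chi-square over 36 bins at N = 2e5
    from scipy.stats import chi2

    from ppgmc.kernel import _seed_state, _spin

    rs = _seed_state(123)
    n = 200_000
    phis = np.empty(n)
    for i in range(n):
        ct = 0.2 if i % 2 == 0 else 0.9  # two fixed polar angles
        ux, uy, uz = _spin(rs, 0.0, 0.0, 1.0, ct)
        phis[i] = math.atan2(uy, ux)
    counts, _ = np.histogram(phis, bins=36, range=(-math.pi, math.pi))
    expected = n / 36
    stat = ((counts - expected) ** 2 / expected).sum()
    assert stat < chi2.ppf(0.999, df=35)


class TestBatchConservation:
    def test_energy_audit(self, scene_520):
        src, det = source_detector_pair(2.0, 15.0, 25.0)
        res = run_batch(200_000, 5, scene_520, src, det)
        assert res.energy_balance == pytest.approx(1.0, abs=5e-3)
        assert res.n_capped == 0

    def test_bitwise_determinism(self, scene_520):
        src, det = source_detector_pair(2.0, 35.0, 35.0)
        a = run_batch(50_000, 9, scene_520, src, det)
        b = run_batch(50_000, 9, scene_520, src, det)
        assert a == b

    def test_diffuse_reflectance_ordering(self):
        # albedo at 940 nm exceeds 520 nm: more light comes back out
        refl = {}
        for wl in (520, 940):
            scene = build_scene(SceneConfig(bare_phantom=True), wl)
            src, det = source_detector_pair(2.0, 0.0, 0.0)
            res = run_batch(100_000, 2, scene, src, det)
            refl[wl] = (
                res.escaped_weight + res.detected_weight
            ) / res.n_photons
        assert refl[940] > refl[520]

    def test_far_roulette_unbiased_bookkeeping(self, scene_940):
        # with and without far-field roulette the audit identity holds and
        # total reflectance agrees within Monte Carlo tolerance
        src, det = source_detector_pair(2.0, 15.0, 25.0)
        on = run_batch(150_000, 4, scene_940, src, det)
        off = run_batch(
            150_000, 4, scene_940, src, det,
            kernel_config=KernelConfig(far_roulette_survival=1.0),
        )
        for r in (on, off):
            assert r.energy_balance == pytest.approx(1.0, abs=5e-3)
        r_on = (on.escaped_weight + on.detected_weight) / on.n_photons
        r_off = (off.escaped_weight + off.detected_weight) / off.n_photons
        assert r_on == pytest.approx(r_off, rel=0.05)
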