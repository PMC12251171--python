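"""Photon-packet random-walk kernel.

Implements the weighted Monte Carlo photon transport through the composite
scene: exponential free-path sampling with interaction coefficient
mu_t = mu_a + mu_s inside the scattering phantom, discrete weight deposits
dw = w * mu_a / mu_t at interaction sites, phase-function spins
(Henyey-Greenstein closed form or tabulated Mie inverse CDF), unpolarized
Fresnel/Snell boundary events, Lambert-Beer attenuation in the
non-scattering superstructure (air gap, glass slides), a perfectly
absorbing barrier, and Russian-roulette termination of low-weight packets.

Per-photon bookkeeping records the in-phantom optical path length ``l``
(the quantity entering the differential pathlength factor l = d * DPF) and
the maximum depth reached inside the phantom.  Both accumulate only while
the packet is inside the phantom material.

Randomness comes from an inline xorshift128+ stream seeded per batch,
giving bitwise-reproducible runs for a given seed.  Besides the low-weight
roulette, a single-shot *far-field* roulette may be applied once to
packets that stray far below or far to the side of the source-detector
region (weight-compensated, hence unbiased); it prunes long random walks
that cannot meaningfully contribute to detection.

The heavy loops are compiled with numba; the module also exposes thin
Python entry points (:func:`trace`, :func:`russian_roulette`,
:func:`interface_event`) used by the test suite and the runner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .scene import AMBIENT, AIR_GAP, BARRIER, GLASS, Scene
from .phase import PhaseFunctionTable, ScattererSpec, mie_phase_table

__all__ = [
    "fresnel_reflectance",
    "russian_roulette",
    "interface_event",
    "trace",
    "run_batch",
    "PhotonState",
    "TerminalEvent",
    "BatchResult",
    "KernelConfig",
    "kernel_arrays",
    "KernelInvariantError",
]

# terminal-event codes
DETECTED = 0
ESCAPED = 1
ABSORBED = 2
ROULETTE_KILLED = 3
SIDE_EXIT = 4

KIND_NAMES = {
    DETECTED: "detected",
    ESCAPED: "escaped",
    ABSORBED: "absorbed",
    ROULETTE_KILLED: "roulette_killed",
    SIDE_EXIT: "side_exit",
}

_EPS_T = 1e-12  # minimum admissible boundary distance [mm]
_NUDGE = 1e-9  # post-boundary advance to land inside the next medium [mm]
_BIG = 1e30
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


class KernelInvariantError(RuntimeError):
    """Raised when a photon state becomes non-finite (hard failure)."""


# ---------------------------------------------------------------------------
# random stream: xorshift128+ with splitmix64 seeding
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_state(seed):
    rs = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rs[i] = t ^ (t >> np.uint64(31))
    if rs[0] == 0 and rs[1] == 0:
        rs[0] = np.uint64(1)
    return rs


@njit(cache=True, fastmath=True, error_model="numpy")
def _rand(rs):
    """Uniform variate in [0, 1)."""
    s1 = rs[0]
    s0 = rs[1]
    rs[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    rs[1] = s1
    return float((s0 + s1) >> np.uint64(11)) * _INV53


@njit(cache=True, fastmath=True, error_model="numpy")
def fresnel_reflectance(n1, n2, cos_incident):
    """Unpolarized Fresnel reflectance; 1.0 beyond the critical angle."""
    ci = cos_incident
    if ci > 1.0:
        ci = 1.0
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, error_model="numpy")
def _mat_above(x, y, z, gap, slide, bhalf, bheight, radius):
    """Material code above the phantom surface (z < 0)."""
    if x * x + y * y > radius * radius:
        return AMBIENT
    if bhalf > 0.0 and abs(x) <= bhalf and z >= -bheight:
        return BARRIER
    if z >= -gap:
        return AIR_GAP
    if z >= -(gap + slide):
        return GLASS
    return AMBIENT


@njit(cache=True, fastmath=True, error_model="numpy")
def _sample_cos_theta(rs, use_table, hg_g, tab_cdf, tab_mu):
    u = _rand(rs)
    if use_table:
        i = np.searchsorted(tab_cdf, u)
        if i <= 0:
            return tab_mu[0]
        if i >= tab_cdf.shape[0]:
            return tab_mu[-1]
        c0 = tab_cdf[i - 1]
        c1 = tab_cdf[i]
        if c1 <= c0:
            return tab_mu[i]
        f = (u - c0) / (c1 - c0)
        return tab_mu[i - 1] + f * (tab_mu[i] - tab_mu[i - 1])
    if hg_g == 0.0:
        return 2.0 * u - 1.0
    s = (1.0 - hg_g * hg_g) / (1.0 - hg_g + 2.0 * hg_g * u)
    ct = (1.0 + hg_g * hg_g - s * s) / (2.0 * hg_g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, fastmath=True, error_model="numpy")
def _spin(rs, ux, uy, uz, ct):
    """Rotate the direction by polar angle acos(ct) and uniform azimuth.

    The azimuth cosine/sine pair comes from Marsaglia's double-angle
    rejection sampler (no trigonometric calls).
    """
    while True:
        a = 2.0 * _rand(rs) - 1.0
        b = 2.0 * _rand(rs) - 1.0
        r2 = a * a + b * b
        if 0.0 < r2 <= 1.0:
            break
    cp = (a * a - b * b) / r2
    sp = 2.0 * a * b / r2
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        tmp = math.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / tmp + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / tmp + uy * ct
        nz = -st * cp * tmp + uz * ct
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True, error_model="numpy")
def _trace_one(
    rs,
    x, y, z, ux, uy, uz, w,
    gap, slide, bhalf, bheight, radius, height,
    n_glass, mua_glass, n_phantom, mua_phantom, mus_phantom,
    use_table, hg_g, tab_cdf, tab_mu,
    rr_threshold, rr_factor,
    far_depth, far_radius, far_survival,
    max_events,
    record, px, pz, pw,
):
    """Follow one photon packet to its terminal event.

    Returns (kind, w, l, max_depth, exit_x, exit_y, exit_ux, exit_uy,
    exit_uz, deposited, rr_killed, rr_gained, n_path, capped).
    The exit record refers to the last upward crossing of the phantom
    surface in air (valid for kind == ESCAPED).
    """
    l = 0.0
    maxd = 0.0
    deposited = 0.0
    killed = 0.0
    gained = 0.0
    sx = 0.0
    sy = 0.0
    sux = 0.0
    suy = 0.0
    suz = 0.0
    n_path = 0
    cap = px.shape[0]

    mut = mua_phantom + mus_phantom
    beer_only = mus_phantom <= 0.0  # non-scattering phantom: pure Lambert-Beer
    in_phantom = z >= 0.0
    far_done = far_survival >= 1.0  # single-shot far-field roulette
    far_r2 = far_radius * far_radius
    events = 0

    if record and in_phantom and n_path < cap:
        px[n_path] = x
        pz[n_path] = z
        pw[n_path] = w
        n_path += 1

    while True:
        if events >= max_events:
            # iteration cap: deposit remainder, count as absorbed
            deposited += w
            return (ABSORBED, 0.0, l, maxd, sx, sy, sux, suy, suz,
                    deposited, killed, gained, n_path, 1)

        if in_phantom:
            if beer_only:
                tau = _BIG  # never interacts; single ray to the boundary
            else:
                tau = -math.log(1.0 - _rand(rs))
            while True:
                events += 1
                if events >= max_events:
                    deposited += w
                    return (ABSORBED, 0.0, l, maxd, sx, sy, sux, suy, suz,
                            deposited, killed, gained, n_path, 1)
                s = tau / mut if not beer_only else _BIG

                # boundary reachability with cheap bounds first
                db = _BIG
                btype = -1
                if uz < 0.0 and z < s:
                    t = -z / uz
                    if t < db:
                        db = t
                        btype = 0
                if uz > 0.0 and z + s > height:
                    t = (height - z) / uz
                    if t < db:
                        db = t
                        btype = 1
                rr2 = x * x + y * y
                margin = radius - s
                if margin < 0.0 or rr2 > margin * margin:
                    a = ux * ux + uy * uy
                    if a > 0.0:
                        b = x * ux + y * uy
                        c = rr2 - radius * radius
                        disc = b * b - a * c
                        if disc > 0.0:
                            t = (-b + math.sqrt(disc)) / a
                            if _EPS_T < t < db:
                                db = t
                                btype = 1

                if s < db:
                    # interaction site
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    l += s
                    if z > maxd:
                        maxd = z
                    dep = w * mua_phantom / mut
                    deposited += dep
                    w -= dep
                    if w < rr_threshold:
                        if _rand(rs) * rr_factor < 1.0:
                            gained += w * (rr_factor - 1.0)
                            w *= rr_factor
                        else:
                            killed += w
                            return (ROULETTE_KILLED, 0.0, l, maxd,
                                    sx, sy, sux, suy, suz,
                                    deposited, killed, gained, n_path, 0)
                    if not far_done and (z > far_depth or rr2 > far_r2):
                        far_done = True
                        if _rand(rs) < far_survival:
                            gained += w * (1.0 / far_survival - 1.0)
                            w /= far_survival
                        else:
                            killed += w
                            return (ROULETTE_KILLED, 0.0, l, maxd,
                                    sx, sy, sux, suy, suz,
                                    deposited, killed, gained, n_path, 0)
                    ct = _sample_cos_theta(rs, use_table, hg_g,
                                           tab_cdf, tab_mu)
                    ux, uy, uz = _spin(rs, ux, uy, uz, ct)
                    if record and n_path < cap:
                        px[n_path] = x
                        pz[n_path] = z
                        pw[n_path] = w
                        n_path += 1
                    tau = -math.log(1.0 - _rand(rs))
                    continue

                # boundary reached first
                x += ux * db
                y += uy * db
                z += uz * db
                l += db
                if z > maxd:
                    maxd = z
                if beer_only:
                    frac = math.exp(-mua_phantom * db)
                    deposited += w * (1.0 - frac)
                    w *= frac
                else:
                    tau -= db * mut
                if btype == 1:
                    # lateral wall or bottom: photon leaves and is lost
                    if record and n_path < cap:
                        px[n_path] = x
                        pz[n_path] = z
                        pw[n_path] = w
                        n_path += 1
                    return (SIDE_EXIT, w, l, maxd, sx, sy, sux, suy, suz,
                            deposited, killed, gained, n_path, 0)
                # top surface: Fresnel phantom -> air
                z = 0.0
                ci = -uz
                rf = fresnel_reflectance(n_phantom, 1.0, ci)
                if _rand(rs) < rf:
                    uz = -uz
                    if record and n_path < cap:
                        px[n_path] = x
                        pz[n_path] = z
                        pw[n_path] = w
                        n_path += 1
                    continue  # carry remaining optical depth
                # refract into air above the surface
                eta = n_phantom / 1.0
                st2 = eta * eta * (1.0 - ci * ci)
                ct_t = math.sqrt(max(0.0, 1.0 - st2))
                nx = ux * eta
                ny = uy * eta
                nz = -ct_t
                norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                ux = nx / norm
                uy = ny / norm
                uz = nz / norm
                sx = x
                sy = y
                sux = ux
                suy = uy
                suz = uz
                if record and n_path < cap:
                    px[n_path] = x
                    pz[n_path] = z
                    pw[n_path] = w
                    n_path += 1
                in_phantom = False
                z = -_NUDGE
                break
            if in_phantom:
                continue
            # fall through to the superstructure loop

        # ---- non-scattering superstructure (z < 0) ----
        events += 1
        m = _mat_above(x, y, z, gap, slide, bhalf, bheight, radius)
        if m == BARRIER:
            deposited += w
            return (ABSORBED, 0.0, l, maxd, sx, sy, sux, suy, suz,
                    deposited, killed, gained, n_path, 0)
        if m == GLASS:
            n_cur = n_glass
            mua = mua_glass
        else:
            n_cur = 1.0
            mua = 0.0

        # candidate crossings: horizontal planes, barrier faces, cylinder
        t_min = _BIG
        btype = -1  # 0: z-plane, 1: x-plane, 2: cylinder
        for zp in (0.0, -gap, -(gap + slide), -bheight):
            if uz != 0.0:
                t = (zp - z) / uz
                if _EPS_T < t < t_min:
                    t_min = t
                    btype = 0
        if bhalf > 0.0 and ux != 0.0:
            for xp in (-bhalf, bhalf):
                t = (xp - x) / ux
                if _EPS_T < t < t_min:
                    # face crossing only matters in the barrier z-range
                    zc = z + uz * t
                    if -bheight <= zc <= 0.0:
                        t_min = t
                        btype = 1
        a = ux * ux + uy * uy
        if a > 0.0:
            b = x * ux + y * uy
            c = x * x + y * y - radius * radius
            disc = b * b - a * c
            if disc > 0.0:
                sq = math.sqrt(disc)
                for t in ((-b - sq) / a, (-b + sq) / a):
                    if _EPS_T < t < t_min:
                        t_min = t
                        btype = 2

        if btype == -1 or (m == AMBIENT and z < -(max(gap + slide, bheight))
                           and uz < 0.0):
            # free flight to infinity
            if uz < 0.0:
                return (ESCAPED, w, l, maxd, sx, sy, sux, suy, suz,
                        deposited, killed, gained, n_path, 0)
            return (SIDE_EXIT, w, l, maxd, sx, sy, sux, suy, suz,
                    deposited, killed, gained, n_path, 0)

        if mua > 0.0:
            frac = math.exp(-mua * t_min)
            deposited += w * (1.0 - frac)
            w *= frac
        x += ux * t_min
        y += uy * t_min
        z += uz * t_min

        xf = x + ux * _NUDGE
        yf = y + uy * _NUDGE
        zf = z + uz * _NUDGE
        if zf >= 0.0:
            # crossed the surface plane downward
            if xf * xf + yf * yf > radius * radius:
                return (SIDE_EXIT, w, l, maxd, sx, sy, sux, suy, suz,
                        deposited, killed, gained, n_path, 0)
            ci = uz
            rf = fresnel_reflectance(n_cur, n_phantom, ci)
            if _rand(rs) < rf:
                uz = -uz
                z = -_NUDGE
                continue
            eta = n_cur / n_phantom
            st2 = eta * eta * (1.0 - ci * ci)
            ct_t = math.sqrt(max(0.0, 1.0 - st2))
            nx = ux * eta
            ny = uy * eta
            nz = ct_t
            norm = math.sqrt(nx * nx + ny * ny + nz * nz)
            ux = nx / norm
            uy = ny / norm
            uz = nz / norm
            z = 0.0
            in_phantom = True
            if record and n_path < cap:
                px[n_path] = x
                pz[n_path] = z
                pw[n_path] = w
                n_path += 1
            continue
        mf = _mat_above(xf, yf, zf, gap, slide, bhalf, bheight, radius)
        if mf == BARRIER:
            deposited += w
            return (ABSORBED, 0.0, l, maxd, sx, sy, sux, suy, suz,
                    deposited, killed, gained, n_path, 0)
        n_far = n_glass if mf == GLASS else 1.0
        if btype == 0 and n_far != n_cur:
            ci = abs(uz)
            rf = fresnel_reflectance(n_cur, n_far, ci)
            if _rand(rs) < rf:
                uz = -uz
            else:
                eta = n_cur / n_far
                st2 = eta * eta * (1.0 - ci * ci)
                ct_t = math.sqrt(max(0.0, 1.0 - st2))
                sgn = 1.0 if uz > 0.0 else -1.0
                nx = ux * eta
                ny = uy * eta
                nz = sgn * ct_t
                norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                ux = nx / norm
                uy = ny / norm
                uz = nz / norm
        # (cylinder-edge and in-plane crossings: no index step applied)
        x += ux * _NUDGE
        y += uy * _NUDGE
        z += uz * _NUDGE


@njit(cache=True, fastmath=True, error_model="numpy")
def _rasterize(px, pz, pw, n_path, grid, x0, z0, cell):
    nmz, nmx = grid.shape
    for i in range(n_path - 1):
        x1 = px[i]
        z1 = pz[i]
        x2 = px[i + 1]
        z2 = pz[i + 1]
        wseg = pw[i]
        seg = math.sqrt((x2 - x1) ** 2 + (z2 - z1) ** 2)
        if seg <= 0.0:
            continue
        nsub = int(seg / (0.5 * cell)) + 1
        ds = seg / nsub
        for k in range(nsub):
            f = (k + 0.5) / nsub
            xm = x1 + f * (x2 - x1)
            zm = z1 + f * (z2 - z1)
            ix = int((xm - x0) / cell)
            iz = int((zm - z0) / cell)
            if 0 <= ix < nmx and 0 <= iz < nmz:
                grid[iz, ix] += wseg * ds


@njit(cache=True, fastmath=True, error_model="numpy")
def _run_batch(
    n_photons, seed,
    src_cx, src_sin, src_cos, src_radius,
    det_cx, det_ax, det_az, det_a, det_b, det_cos_alpha,
    gap, slide, bhalf, bheight, radius, height,
    n_glass, mua_glass, n_phantom, mua_phantom, mus_phantom,
    use_table, hg_g, tab_cdf, tab_mu,
    rr_threshold, rr_factor,
    far_depth, far_radius, far_survival,
    max_events,
    record, grid, map_x0, map_z0, map_cell,
    px, pz, pw,
):
    rs = _seed_state(seed)
    detected_w = 0.0
    det_wl = 0.0
    det_wd = 0.0
    n_det = 0
    escaped_w = 0.0
    n_esc = 0
    side_w = 0.0
    n_side = 0
    deposited = 0.0
    killed = 0.0
    gained = 0.0
    n_abs = 0
    n_rr = 0
    n_capped = 0

    for _ in range(n_photons):
        r = src_radius * math.sqrt(_rand(rs))
        ang = 2.0 * math.pi * _rand(rs)
        lx = src_cx + r * math.cos(ang) / src_cos
        ly = r * math.sin(ang)
        # first interface: air -> phantom at the surface spot
        rf = fresnel_reflectance(1.0, n_phantom, src_cos)
        if _rand(rs) < rf:
            escaped_w += 1.0
            n_esc += 1
            continue
        eta = 1.0 / n_phantom
        sux0 = src_sin * eta
        suz0 = math.sqrt(max(0.0, 1.0 - sux0 * sux0))
        (kind, wf, l, maxd, ex, ey, eux, euy, euz,
         dep, kil, gai, n_path, capped) = _trace_one(
            rs,
            lx, ly, 0.0, sux0, 0.0, suz0, 1.0,
            gap, slide, bhalf, bheight, radius, height,
            n_glass, mua_glass, n_phantom, mua_phantom, mus_phantom,
            use_table, hg_g, tab_cdf, tab_mu,
            rr_threshold, rr_factor,
            far_depth, far_radius, far_survival,
            max_events,
            record, px, pz, pw,
        )
        deposited += dep
        killed += kil
        gained += gai
        n_capped += capped
        if kind == ESCAPED:
            rx = (ex - det_cx) / det_a
            ry = ey / det_b
            cosang = eux * det_ax + euz * det_az
            if rx * rx + ry * ry <= 1.0 and cosang >= det_cos_alpha:
                detected_w += wf
                det_wl += wf * l
                det_wd += wf * maxd
                n_det += 1
                if record:
                    _rasterize(px, pz, pw, n_path, grid,
                               map_x0, map_z0, map_cell)
            else:
                escaped_w += wf
                n_esc += 1
        elif kind == ABSORBED:
            n_abs += 1
        elif kind == ROULETTE_KILLED:
            n_rr += 1
        else:
            side_w += wf
            n_side += 1

    return (detected_w, det_wl, det_wd, n_det, escaped_w, n_esc,
            side_w, n_side, deposited, killed, gained, n_abs, n_rr, n_capped)


# ---------------------------------------------------------------------------
# Python-level API
# ---------------------------------------------------------------------------


@dataclass
class PhotonState:
    """Mutable packet state used at the Python level (launch/tests).

    The compiled kernel tracks the same quantities as scalars; ``l`` and
    ``max_depth`` accumulate only inside the phantom.
    """

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    path_length: float = 0.0
    max_depth: float = 0.0
    alive: bool = True
    current_material: str = "air"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isfinite(norm) or norm == 0.0:
            raise KernelInvariantError("photon direction must be finite and nonzero")
        self.direction = self.direction / norm


@dataclass(frozen=True)
class TerminalEvent:
    """Outcome of one photon packet (exactly one per launched photon)."""

    kind: str
    weight: float
    path_length: float
    max_depth: float
    exit_position: tuple[float, float] | None
    exit_direction: tuple[float, float, float] | None
    deposited: float = 0.0
    capped: bool = False


@dataclass(frozen=True)
class BatchResult:
    """Aggregate tallies of one seed's photon batch."""

    n_photons: int
    detected_weight: float
    detected_weight_path: float  # sum of w * l over detected packets
    detected_weight_depth: float  # sum of w * max_depth
    n_detected: int
    escaped_weight: float
    n_escaped: int
    side_exit_weight: float
    n_side_exit: int
    deposited_weight: float
    roulette_killed_weight: float
    roulette_gained_weight: float
    n_absorbed: int
    n_roulette: int
    n_capped: int

    @property
    def energy_balance(self) -> float:
        """(detected + escaped + side + deposited + killed - gained) / launched."""
        total = (
            self.detected_weight
            + self.escaped_weight
            + self.side_exit_weight
            + self.deposited_weight
            + self.roulette_killed_weight
            - self.roulette_gained_weight
        )
        return total / self.n_photons


@dataclass(frozen=True)
class KernelConfig:
    """Numeric knobs of the random walk.

    The far-field roulette is applied at most once per packet, when it
    first scatters deeper than ``far_roulette_depth`` or laterally beyond
    ``far_roulette_radius`` from the scene centre: the packet survives
    with probability ``far_roulette_survival`` and its weight is divided
    by that probability (set the survival to 1 to disable).
    """

    rr_threshold: float = 1e-4
    rr_survival_factor: float = 10.0
    far_roulette_depth: float = 15.0  # mm
    far_roulette_radius: float = 18.0  # mm
    far_roulette_survival: float = 0.2
    max_events: int = 1_000_000


_EMPTY = np.zeros(2, dtype=np.float64)


def kernel_arrays(scene: Scene, backend: str = "hg",
                  mie_table: PhaseFunctionTable | None = None):
    """Scalar/array kernel parameters for a scene and phase backend.

    Returns (geom, mats, use_table, hg_g, tab_cdf, tab_mu).  With the Mie
    backend, mu_s is derived from the measured mu_s' using the
    Mie-computed mean cosine, keeping the transport scattering fixed.
    """
    cfg = scene.config
    props = scene.phantom.properties
    if backend == "hg":
        use_table = False
        g = props.g
        mus = props.mu_s_reduced / (1.0 - g)
        tab_cdf = _EMPTY
        tab_mu = _EMPTY
    elif backend == "mie":
        if mie_table is None:
            mie_table = mie_phase_table(
                ScattererSpec(wavelength_nm=scene.wavelength,
                              host_index=props.n)
            )
        use_table = True
        g = 0.0
        mus = props.mu_s_reduced / (1.0 - mie_table.mean_cos)
        tab_cdf = np.ascontiguousarray(mie_table.cdf)
        tab_mu = np.ascontiguousarray(mie_table.cos_theta_grid)
    else:
        raise ValueError(f"unknown phase backend {backend!r}")

    if cfg.bare_phantom:
        geom = (0.0, 0.0, 0.0, 0.0, cfg.phantom_radius, cfg.phantom_height)
    else:
        geom = (
            cfg.air_gap_thickness,
            cfg.slide_thickness,
            0.5 * cfg.barrier_thickness,
            cfg.barrier_height,
            cfg.phantom_radius,
            cfg.phantom_height,
        )
    glass = scene.glass.properties
    mats = (glass.n, glass.mu_a, props.n, props.mu_a, mus)
    return geom, mats, use_table, g, tab_cdf, tab_mu


def russian_roulette(w: float, u: float, threshold: float = 1e-4,
                     survival_factor: float = 10.0):
    """Unbiased roulette: returns (weight, alive) for a uniform variate u."""
    if w >= threshold:
        return w, True
    if u * survival_factor < 1.0:
        return w * survival_factor, True
    return 0.0, False


def interface_event(direction, normal, n1: float, n2: float, u: float):
    """Statistical reflect/refract decision at a planar boundary.

    ``direction`` must point into the surface (direction . normal > 0 with
    ``normal`` oriented from medium 1 into medium 2).  Returns
    (new_direction, reflected_flag).
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    d = d / np.linalg.norm(d)
    nrm = nrm / np.linalg.norm(nrm)
    ci = float(np.dot(d, nrm))
    if ci <= 0.0:
        raise ValueError("direction must point into the interface")
    r = fresnel_reflectance(n1, n2, ci)
    if u < r:
        out = d - 2.0 * ci * nrm
        return out / np.linalg.norm(out), True
    eta = n1 / n2
    st2 = eta * eta * (1.0 - ci * ci)
    ct = math.sqrt(max(0.0, 1.0 - st2))
    out = eta * d + (ct - eta * ci) * nrm
    return out / np.linalg.norm(out), False


def _kernel_tuple(cfg: KernelConfig):
    return (
        cfg.rr_threshold,
        cfg.rr_survival_factor,
        cfg.far_roulette_depth,
        cfg.far_roulette_radius,
        cfg.far_roulette_survival,
        cfg.max_events,
    )


def trace(
    position,
    direction,
    scene: Scene,
    weight: float = 1.0,
    backend: str = "hg",
    seed: int = 0,
    kernel_config: KernelConfig = KernelConfig(),
    mie_table: PhaseFunctionTable | None = None,
) -> TerminalEvent:
    """Trace a single photon packet from an arbitrary initial state.

    The packet starts inside the phantom when z >= 0 and in the
    superstructure otherwise.  Used by tests and debugging; sweeps go
    through the batch runner.
    """
    x, y, z = (float(v) for v in position)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if not np.all(np.isfinite([x, y, z, weight])) or not np.all(np.isfinite(d)):
        raise KernelInvariantError("non-finite initial photon state")
    geom, mats, use_table, g, tab_cdf, tab_mu = kernel_arrays(
        scene, backend, mie_table
    )
    rs = _seed_state(seed)
    buf = np.zeros(1, dtype=np.float64)
    (kind, wf, l, maxd, sx, sy, sux, suy, suz,
     dep, _kil, _gai, _np_, capped) = _trace_one(
        rs,
        x, y, z, d[0], d[1], d[2], float(weight),
        *geom, *mats,
        use_table, g, tab_cdf, tab_mu,
        *_kernel_tuple(kernel_config),
        False, buf, buf, buf,
    )
    has_exit = kind == ESCAPED
    return TerminalEvent(
        kind=KIND_NAMES[kind],
        weight=wf,
        path_length=l,
        max_depth=maxd,
        exit_position=(sx, sy) if has_exit else None,
        exit_direction=(sux, suy, suz) if has_exit else None,
        deposited=dep,
        capped=bool(capped),
    )


def run_batch(
    n_photons: int,
    seed: int,
    scene: Scene,
    source,
    detector,
    backend: str = "hg",
    kernel_config: KernelConfig = KernelConfig(),
    mie_table: PhaseFunctionTable | None = None,
    density_grid: np.ndarray | None = None,
    density_extent=None,
    path_capacity: int = 8192,
) -> BatchResult:
    """Run one seed's batch of photon packets through the scene.

    ``source`` and ``detector`` are the configs from
    :mod:`ppgmc.optics`.  When ``density_grid`` is given (2-D array,
    rows = z, cols = x) the phantom path segments of detected photons are
    accumulated into it, weighted by packet weight times path length;
    ``density_extent`` = (x0, z0, cell_mm).
    """
    geom, mats, use_table, g, tab_cdf, tab_mu = kernel_arrays(
        scene, backend, mie_table
    )
    theta_s = math.radians(source.theta_s)
    theta_d = math.radians(detector.theta_d)
    record = density_grid is not None
    if record:
        x0, z0, cell = density_extent
        grid = density_grid
        px = np.zeros(path_capacity, dtype=np.float64)
        pz = np.zeros(path_capacity, dtype=np.float64)
        pw = np.zeros(path_capacity, dtype=np.float64)
    else:
        x0 = z0 = 0.0
        cell = 1.0
        grid = np.zeros((1, 1), dtype=np.float64)
        px = pz = pw = np.zeros(1, dtype=np.float64)

    out = _run_batch(
        int(n_photons), int(seed),
        source.spot_center[0], math.sin(theta_s), math.cos(theta_s),
        0.5 * source.spot_diameter,
        detector.spot_center[0],
        math.sin(theta_d), -math.cos(theta_d),
        0.5 * detector.spot_diameter / math.cos(theta_d),
        0.5 * detector.spot_diameter,
        math.cos(math.radians(detector.acceptance_half_angle)),
        *geom, *mats,
        use_table, g, tab_cdf, tab_mu,
        *_kernel_tuple(kernel_config),
        record, grid, x0, z0, cell,
        px, pz, pw,
    )
    (detected_w, det_wl, det_wd, n_det, escaped_w, n_esc, side_w, n_side,
     deposited, rr_killed, rr_gained, n_abs, n_rr, n_capped) = out
    return BatchResult(
        n_photons=int(n_photons),
        detected_weight=detected_w,
        detected_weight_path=det_wl,
        detected_weight_depth=det_wd,
        n_detected=n_det,
        escaped_weight=escaped_w,
        n_escaped=n_esc,
        side_exit_weight=side_w,
        n_side_exit=n_side,
        deposited_weight=deposited,
        roulette_killed_weight=rr_killed,
        roulette_gained_weight=rr_gained,
        n_absorbed=n_abs,
        n_roulette=n_rr,
        n_capped=n_capped,
    )
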