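"""Sweep orchestration: DC level, DPF, penetration depth, density maps.

A *configuration* is one tuple (wavelength, source-detector distance d,
source angle theta_s, detector angle theta_d).  Each configuration is
simulated as ``n_seeds`` independent replicates whose detected weights
are averaged; the total photon budget N(d) = N0 * d / d_ref grows
linearly with distance (d_ref = 2 mm, the smallest distance studied) and
is split evenly across the replicates.

Per configuration the runner reports:

* the DC level S_bar: mean over seeds of (sum of detected packet weight)
  divided by the photons launched per seed;
* the differential pathlength factor DPF = <l>_w / d, where <l>_w is the
  weight-averaged in-phantom path length of detected packets (Eq. l = d*DPF);
* the weight-averaged maximum penetration depth of detected packets.

Normalised levels S_bar' divide each row by the reference configuration
of its branch: (theta_s, theta_d) = (15, 25) for positive angles and
(-15, -25) for negative angles, per (wavelength, d).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kernel import KernelConfig, run_batch
from .optics import source_detector_pair
from .phase import PhaseFunctionTable, ScattererSpec, mie_phase_table
from .scene import Scene, SceneConfig, build_scene

__all__ = [
    "SweepConfig",
    "SimulationResult",
    "DensityMap",
    "NormalizationError",
    "EmptyMapError",
    "run_configuration",
    "run_sweep",
    "normalize",
    "distance_attenuation",
    "build_density_map",
    "write_outputs",
    "POSITIVE_REFERENCE",
    "NEGATIVE_REFERENCE",
]

D_REF = 2.0  # mm; photon budgets scale as N0 * d / D_REF
POSITIVE_REFERENCE = (15.0, 25.0)
NEGATIVE_REFERENCE = (-15.0, -25.0)

TABLE_COLUMNS = [
    "wavelength_nm",
    "distance_mm",
    "theta_s_deg",
    "theta_d_deg",
    "branch",
    "n_photons_total",
    "n_seeds",
    "s_bar",
    "s_bar_se",
    "s_bar_prime",
    "dpf",
    "dpf_se",
    "mean_max_depth_mm",
    "mean_max_depth_se",
    "n_detected",
]


class NormalizationError(KeyError):
    """Raised when the reference configuration of a branch is missing."""


class EmptyMapError(RuntimeError):
    """Raised when no detected photon contributed to a density map."""


def _branch(theta_s: float, theta_d: float) -> str:
    return "negative" if (theta_s < 0 or theta_d < 0) else "positive"


@dataclass(frozen=True)
class SweepConfig:
    """Grid and budget of a simulation sweep."""

    wavelengths: tuple[int, ...] = (520, 637, 940)
    distances: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    theta_s_positive: tuple[float, ...] = (0.0, 15.0, 25.0, 35.0, 45.0, 55.0)
    theta_d_positive: tuple[float, ...] = (0.0, 25.0, 35.0, 45.0, 55.0)
    theta_s_negative: tuple[float, ...] = (-15.0, -25.0, -35.0, -45.0, -55.0)
    theta_d_negative: tuple[float, ...] = (-25.0, -35.0, -45.0, -55.0)
    photons_base: int = 2_000_000  # total per configuration at d = D_REF
    n_seeds: int = 5
    base_seed: int = 1
    phase_backend: str = "hg"
    acceptance_half_angle: float = 30.0
    scene: SceneConfig = field(default_factory=SceneConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)

    def n_photons(self, distance: float) -> int:
        """Total photon budget for one configuration at distance d."""
        return int(round(self.photons_base * distance / D_REF))

    def angle_pairs(self, branch: str = "both"):
        pos = [
            (ts, td)
            for ts in self.theta_s_positive
            for td in self.theta_d_positive
        ]
        neg = [
            (ts, td)
            for ts in self.theta_s_negative
            for td in self.theta_d_negative
        ]
        if branch == "positive":
            return pos
        if branch == "negative":
            return neg
        return pos + neg


@dataclass
class SimulationResult:
    """Seed-averaged metrics of one configuration."""

    wavelength: int
    distance: float
    theta_s: float
    theta_d: float
    backend: str
    n_photons_total: int
    n_seeds: int
    s_bar: float
    s_bar_se: float
    dpf: float
    dpf_se: float
    mean_max_depth: float
    mean_max_depth_se: float
    n_detected: int
    per_seed_s: np.ndarray
    per_seed_n_detected: np.ndarray
    per_seed_dpf: np.ndarray
    per_seed_depth: np.ndarray
    seeds: np.ndarray
    flagged_no_detection: bool = False

    @property
    def branch(self) -> str:
        return _branch(self.theta_s, self.theta_d)


def _config_seed(base_seed: int, wavelength: int, distance: float,
                 theta_s: float, theta_d: float, rep: int,
                 mirror: bool = False) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    key = [
        int(base_seed),
        int(wavelength),
        int(round(distance * 1000)),
        int(round(theta_s * 10)) + 3600,
        int(round(theta_d * 10)) + 3600,
        int(rep),
        int(mirror),
    ]
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


_MIE_CACHE: dict[tuple[int, float], PhaseFunctionTable] = {}


def _mie_table_for(scene: Scene) -> PhaseFunctionTable:
    key = (scene.wavelength, scene.phantom.properties.n)
    if key not in _MIE_CACHE:
        _MIE_CACHE[key] = mie_phase_table(
            ScattererSpec(wavelength_nm=scene.wavelength,
                          host_index=scene.phantom.properties.n)
        )
    return _MIE_CACHE[key]


def run_configuration(
    wavelength: int,
    distance: float,
    theta_s: float,
    theta_d: float,
    sweep: SweepConfig,
    scene: Scene | None = None,
    mirror: bool = False,
    density_grid: np.ndarray | None = None,
    density_extent=None,
) -> SimulationResult:
    """Simulate one (wavelength, d, theta_s, theta_d) configuration."""
    if scene is None:
        scene = build_scene(sweep.scene, wavelength)
    mie_table = (
        _mie_table_for(scene) if sweep.phase_backend == "mie" else None
    )
    src, det = source_detector_pair(
        distance, theta_s, theta_d, wavelength=wavelength,
        acceptance_half_angle=sweep.acceptance_half_angle, mirror=mirror,
    )
    n_total = sweep.n_photons(distance)
    n_seed = max(1, n_total // sweep.n_seeds)

    per_s = np.zeros(sweep.n_seeds)
    per_n = np.zeros(sweep.n_seeds, dtype=np.int64)
    per_dpf = np.full(sweep.n_seeds, np.nan)
    per_depth = np.full(sweep.n_seeds, np.nan)
    seeds = np.zeros(sweep.n_seeds, dtype=np.int64)
    wl_sum = 0.0
    wd_sum = 0.0
    w_sum = 0.0
    for rep in range(sweep.n_seeds):
        seed = _config_seed(sweep.base_seed, wavelength, distance,
                            theta_s, theta_d, rep, mirror)
        seeds[rep] = seed
        res = run_batch(
            n_seed, seed, scene, src, det,
            backend=sweep.phase_backend,
            kernel_config=sweep.kernel,
            mie_table=mie_table,
            density_grid=density_grid,
            density_extent=density_extent,
        )
        per_s[rep] = res.detected_weight / n_seed
        per_n[rep] = res.n_detected
        if res.detected_weight > 0:
            per_dpf[rep] = (
                res.detected_weight_path / res.detected_weight / distance
            )
            per_depth[rep] = res.detected_weight_depth / res.detected_weight
        wl_sum += res.detected_weight_path
        wd_sum += res.detected_weight_depth
        w_sum += res.detected_weight

    s_bar = float(per_s.mean())
    s_bar_se = (
        float(per_s.std(ddof=1) / math.sqrt(sweep.n_seeds))
        if sweep.n_seeds > 1
        else float("nan")
    )
    n_det = int(per_n.sum())
    if n_det == 0:
        dpf = float("nan")
        depth = float("nan")
        dpf_se = float("nan")
        depth_se = float("nan")
        flagged = True
    else:
        dpf = wl_sum / w_sum / distance
        depth = wd_sum / w_sum
        good_dpf = per_dpf[np.isfinite(per_dpf)]
        good_dep = per_depth[np.isfinite(per_depth)]
        dpf_se = (
            float(good_dpf.std(ddof=1) / math.sqrt(len(good_dpf)))
            if len(good_dpf) > 1 else float("nan")
        )
        depth_se = (
            float(good_dep.std(ddof=1) / math.sqrt(len(good_dep)))
            if len(good_dep) > 1 else float("nan")
        )
        flagged = False
    return SimulationResult(
        wavelength=wavelength,
        distance=distance,
        theta_s=theta_s,
        theta_d=theta_d,
        backend=sweep.phase_backend,
        n_photons_total=n_seed * sweep.n_seeds,
        n_seeds=sweep.n_seeds,
        s_bar=s_bar,
        s_bar_se=s_bar_se,
        dpf=dpf,
        dpf_se=dpf_se,
        mean_max_depth=depth,
        mean_max_depth_se=depth_se,
        n_detected=n_det,
        per_seed_s=per_s,
        per_seed_n_detected=per_n,
        per_seed_dpf=per_dpf,
        per_seed_depth=per_depth,
        seeds=seeds,
        flagged_no_detection=flagged,
    )


def _result_row(r: SimulationResult) -> dict:
    return {
        "wavelength_nm": r.wavelength,
        "distance_mm": r.distance,
        "theta_s_deg": r.theta_s,
        "theta_d_deg": r.theta_d,
        "branch": r.branch,
        "n_photons_total": r.n_photons_total,
        "n_seeds": r.n_seeds,
        "s_bar": r.s_bar,
        "s_bar_se": r.s_bar_se,
        "s_bar_prime": float("nan"),
        "dpf": r.dpf,
        "dpf_se": r.dpf_se,
        "mean_max_depth_mm": r.mean_max_depth,
        "mean_max_depth_se": r.mean_max_depth_se,
        "n_detected": r.n_detected,
    }


def run_sweep(sweep: SweepConfig, pairs=None, progress=None) -> pd.DataFrame:
    """Run the full (or a reduced) grid and return the sweep table.

    ``pairs`` optionally restricts the angle grid to an explicit list of
    (theta_s, theta_d) tuples (e.g. the reduced diagonal used for quick
    distance-attenuation estimates).  Rows are ordered deterministically
    by (wavelength, distance, theta_s, theta_d).
    """
    rows = []
    for wl in sweep.wavelengths:
        scene = build_scene(sweep.scene, wl)
        for d in sweep.distances:
            plist = pairs if pairs is not None else sweep.angle_pairs()
            for ts, td in plist:
                res = run_configuration(wl, d, ts, td, sweep, scene=scene)
                rows.append(_result_row(res))
                if progress is not None:
                    progress(res)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df = df.sort_values(
        ["wavelength_nm", "distance_mm", "theta_s_deg", "theta_d_deg"]
    ).reset_index(drop=True)
    return normalize(df)


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Attach S_bar' = S_bar / S_bar(reference) per (wavelength, d, branch).

    The positive branch (including 0 deg rows) is referenced to
    (15, 25); the negative branch to (-15, -25).  A missing reference for
    any populated (wavelength, d, branch) raises NormalizationError.
    """
    df = table.copy()
    prime = np.full(len(df), np.nan)
    for (wl, d, br), idx in df.groupby(
        ["wavelength_nm", "distance_mm", "branch"]
    ).groups.items():
        ref_ts, ref_td = (
            POSITIVE_REFERENCE if br == "positive" else NEGATIVE_REFERENCE
        )
        sel = df.loc[idx]
        ref = sel[
            (sel["theta_s_deg"] == ref_ts) & (sel["theta_d_deg"] == ref_td)
        ]
        if len(ref) == 0:
            raise NormalizationError(
                f"missing normalisation configuration (theta_s={ref_ts}, "
                f"theta_d={ref_td}) for wavelength={wl} nm, d={d} mm, "
                f"branch={br}"
            )
        ref_val = float(ref["s_bar"].iloc[0])
        prime[np.asarray(idx)] = sel["s_bar"].to_numpy() / ref_val
    df["s_bar_prime"] = prime
    return df


def distance_attenuation(
    table: pd.DataFrame, wavelength: int,
    d_near: float = 2.0, d_far: float = 5.0,
) -> float:
    """Mean ratio S_bar(d_far)/S_bar(d_near) over positive-angle configs.

    This is the distance-attenuation factor reported per wavelength; the
    mean runs over the positive (theta_s, theta_d) configurations present
    at both distances.
    """
    sel = table[
        (table["wavelength_nm"] == wavelength)
        & (table["branch"] == "positive")
        & (table["theta_s_deg"] > 0)
        & (table["theta_d_deg"] > 0)
    ]
    near = sel[sel["distance_mm"] == d_near].set_index(
        ["theta_s_deg", "theta_d_deg"]
    )["s_bar"]
    far = sel[sel["distance_mm"] == d_far].set_index(
        ["theta_s_deg", "theta_d_deg"]
    )["s_bar"]
    common = near.index.intersection(far.index)
    if len(common) == 0:
        raise ValueError(
            f"no shared positive-angle configurations at d={d_near} and "
            f"d={d_far} mm for wavelength {wavelength} nm"
        )
    ratios = far.loc[common].to_numpy() / near.loc[common].to_numpy()
    return float(np.mean(ratios))


@dataclass
class DensityMap:
    """Photon 'banana' map: visited weight x path length on an (x, z) grid."""

    grid: np.ndarray  # [nz, nx], z increasing downward
    x_min: float
    x_max: float
    z_min: float
    z_max: float
    cell: float
    wavelength: int
    distance: float
    theta_s: float
    theta_d: float
    n_detected: int
    reference_max: float | None = None

    @property
    def normalized(self) -> np.ndarray:
        ref = self.reference_max if self.reference_max else self.grid.max()
        if ref <= 0:
            raise EmptyMapError("density map has no accumulated weight")
        return self.grid / ref

    def weighted_mean_depth(self) -> float:
        z_centers = self.z_min + (np.arange(self.grid.shape[0]) + 0.5) * self.cell
        tot = self.grid.sum()
        if tot <= 0:
            raise EmptyMapError("density map has no accumulated weight")
        return float((self.grid.sum(axis=1) * z_centers).sum() / tot)


def build_density_map(
    wavelength: int,
    distance: float,
    theta_s: float,
    theta_d: float,
    sweep: SweepConfig,
    x_range: tuple[float, float] = (-5.0, 5.0),
    z_range: tuple[float, float] = (0.0, 10.0),
    cell: float = 0.1,
    scene: Scene | None = None,
) -> DensityMap:
    """Accumulate detected-photon path density for one configuration.

    Raises EmptyMapError when no photon of the run was detected.
    """
    nx = int(round((x_range[1] - x_range[0]) / cell))
    nz = int(round((z_range[1] - z_range[0]) / cell))
    grid = np.zeros((nz, nx), dtype=np.float64)
    res = run_configuration(
        wavelength, distance, theta_s, theta_d, sweep, scene=scene,
        density_grid=grid, density_extent=(x_range[0], z_range[0], cell),
    )
    if res.n_detected == 0 or grid.max() <= 0:
        raise EmptyMapError(
            f"no detected photons for map (wavelength={wavelength}, "
            f"d={distance}, theta_s={theta_s}, theta_d={theta_d})"
        )
    return DensityMap(
        grid=grid,
        x_min=x_range[0],
        x_max=x_range[1],
        z_min=z_range[0],
        z_max=z_range[1],
        cell=cell,
        wavelength=wavelength,
        distance=distance,
        theta_s=theta_s,
        theta_d=theta_d,
        n_detected=res.n_detected,
    )


def write_outputs(
    table: pd.DataFrame,
    out_dir,
    sweep: SweepConfig | None = None,
    maps: dict[str, DensityMap] | None = None,
) -> dict[str, str]:
    """Write the sweep table, density maps and run metadata.

    The table goes to ``sweep_table.csv`` with a stable column order;
    each map to ``density_<name>.csv`` (plain text) plus a sidecar JSON;
    configuration and per-row counts to ``run_metadata.json``.  Returns
    the mapping of logical name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    table_path = out / "sweep_table.csv"
    # %.17g guarantees binary round-trip of float64 values
    table.to_csv(table_path, index=False, columns=TABLE_COLUMNS,
                 float_format="%.17g")
    written["sweep_table"] = str(table_path)

    if maps:
        for name, dm in maps.items():
            mpath = out / f"density_{name}.csv"
            np.savetxt(mpath, dm.grid, delimiter=",")
            meta = {
                k: getattr(dm, k)
                for k in ("x_min", "x_max", "z_min", "z_max", "cell",
                          "wavelength", "distance", "theta_s", "theta_d",
                          "n_detected", "reference_max")
            }
            jpath = out / f"density_{name}.json"
            jpath.write_text(json.dumps(meta, indent=2))
            written[f"density_{name}"] = str(mpath)

    meta = {
        "columns": TABLE_COLUMNS,
        "n_rows": int(len(table)),
        "counts": {
            "n_detected_total": int(table["n_detected"].sum()),
            "n_photons_total": int(table["n_photons_total"].sum()),
        },
    }
    if sweep is not None:
        cfg = asdict(sweep)
        meta["sweep_config"] = cfg
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    written["run_metadata"] = str(meta_path)
    return written
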