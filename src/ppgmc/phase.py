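"""Scattering-angle sampling: Henyey-Greenstein and Mie backends.

The phantom's scatterers are 250 nm TiO2 spheres embedded in an epoxy host.
Two phase functions are supported:

* Henyey-Greenstein (HG) with the characterised anisotropy g = 0.550,
  sampled by its closed-form inverse CDF;
* the exact Mie phase function of a single sphere, computed from the
  Bohren-Huffman amplitude series with the TiO2 refractive index from the
  DeVore dispersion relation (rutile, ordinary ray) and the host index of
  the phantom, sampled by a tabulated inverse CDF.

Both backends return the cosine of the polar deflection angle; azimuth is
sampled uniformly and independently by the transport kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ScattererSpec",
    "PhaseFunctionTable",
    "sample_hg",
    "sample_table",
    "mie_phase_table",
    "devore_tio2_index",
    "mie_s1_s2",
]


def devore_tio2_index(wavelength_nm: float, polymorph: str = "rutile") -> float:
    """Refractive index of TiO2 from the DeVore dispersion relation.

    Rutile, ordinary ray:  n^2 = 5.913 + 0.2441 / (lambda^2 - 0.0803),
    lambda in micrometres.  Valid through the visible and near infrared.
    """
    if polymorph == "rutile":
        lam2 = (wavelength_nm * 1e-3) ** 2
        return float(np.sqrt(5.913 + 0.2441 / (lam2 - 0.0803)))
    if polymorph == "anatase":
        raise NotImplementedError(
            "anatase dispersion constants are not bundled; use polymorph='rutile'"
        )
    raise ValueError(f"unknown TiO2 polymorph {polymorph!r}")


@dataclass(frozen=True)
class ScattererSpec:
    """Single-sphere scatterer: 250 nm TiO2 in the phantom's epoxy host."""

    wavelength_nm: float
    host_index: float
    particle_diameter_nm: float = 250.0
    particle_index: float | None = None  # default: DeVore rutile at wavelength

    def __post_init__(self) -> None:
        if self.particle_diameter_nm <= 0:
            raise ValueError("particle diameter must be positive")
        if self.host_index < 1.0:
            raise ValueError("host refractive index must be >= 1")
        if self.particle_index is not None and self.particle_index < 1.0:
            raise ValueError("particle refractive index must be >= 1")

    @property
    def size_parameter(self) -> float:
        """x = pi * D * n_host / lambda_vacuum."""
        return float(
            np.pi * self.particle_diameter_nm * self.host_index / self.wavelength_nm
        )

    @property
    def relative_index(self) -> float:
        n_p = (
            self.particle_index
            if self.particle_index is not None
            else devore_tio2_index(self.wavelength_nm)
        )
        return n_p / self.host_index


@dataclass(frozen=True)
class PhaseFunctionTable:
    """Tabulated azimuthally-integrated phase function p(cos theta).

    Normalised so that the integral of ``pdf`` over cos theta on [-1, 1]
    is 1; ``cdf`` is the matching cumulative distribution with cdf[0] = 0
    and cdf[-1] = 1.
    """

    cos_theta_grid: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    mean_cos: float
    metadata: dict

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cdf) < 0):
            raise ValueError("cdf must be monotone non-decreasing")
        if abs(self.cdf[0]) > 1e-12 or abs(self.cdf[-1] - 1.0) > 1e-9:
            raise ValueError("cdf must run from 0 to 1")


def sample_hg(g: float, u):
    """Sample cos theta from the Henyey-Greenstein phase function.

    Closed-form inverse CDF; ``u`` may be a scalar or array of uniform
    variates in [0, 1).  For g = 0 the mapping is cos theta = 2u - 1.
    """
    if not abs(g) < 1.0:
        raise ValueError("HG anisotropy must satisfy |g| < 1")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u >= 1.0):
        raise ValueError("uniform variate must lie in [0, 1)")
    if g == 0.0:
        ct = 2.0 * u - 1.0
    else:
        s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - s * s) / (2.0 * g)
    ct = np.clip(ct, -1.0, 1.0)
    return float(ct) if ct.ndim == 0 else ct


def mie_s1_s2(m: float, x: float, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mie scattering amplitudes S1, S2 at cosines ``mu``.

    Standard Bohren-Huffman formulation: logarithmic-derivative downward
    recurrence for D_n, upward Riccati-Bessel recurrences for psi_n and
    chi_n, and the angular functions pi_n, tau_n.  ``m`` is the (real)
    refractive index of the sphere relative to the host and ``x`` the size
    parameter in the host medium.
    """
    if m < 0 or x <= 0:
        raise ValueError("need m > 0 and x > 0")
    mu = np.asarray(mu, dtype=float)
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = max(nmax, int(np.ceil(abs(m * x)))) + 16

    # log-derivative by downward recurrence
    d = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    # Riccati-Bessel psi (regular) and chi (irregular) by upward recurrence
    psi0, psi1 = np.cos(x), np.sin(x)
    chi0, chi1 = -np.sin(x), np.cos(x)
    xi1 = complex(psi1, -chi1)

    an = np.zeros(nmax, dtype=complex)
    bn = np.zeros(nmax, dtype=complex)
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = complex(psi, -chi)
        dn = d[n]
        an[n - 1] = ((dn / m + n / x) * psi - psi1) / ((dn / m + n / x) * xi - xi1)
        bn[n - 1] = ((dn * m + n / x) * psi - psi1) / ((dn * m + n / x) * xi - xi1)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
        xi1 = xi

    s1 = np.zeros(mu.shape, dtype=complex)
    s2 = np.zeros(mu.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (an[n - 1] * pi_n + bn[n - 1] * tau_n)
        s2 += f * (an[n - 1] * tau_n + bn[n - 1] * pi_n)
        pi_np1 = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_np1
    return s1, s2


def mie_phase_table(spec: ScattererSpec, n_grid_points: int = 2048) -> PhaseFunctionTable:
    """Build the tabulated Mie phase function for one scatterer spec.

    Gauss-Legendre nodes on cos theta give the quadrature for the
    normalisation and the mean cosine; the sampling CDF is assembled on
    the same grid (endpoints -1 and +1 appended) by trapezoidal
    accumulation with linear interpolation between nodes.
    """
    if n_grid_points < 512:
        raise ValueError("need at least 512 grid points for a usable table")
    x = spec.size_parameter
    m = spec.relative_index

    nodes, weights = np.polynomial.legendre.leggauss(n_grid_points)
    s1, s2 = mie_s1_s2(m, x, nodes)
    intensity = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    norm = float(np.sum(weights * intensity))
    pdf_nodes = intensity / norm
    mean_cos = float(np.sum(weights * nodes * pdf_nodes))

    # extend to the closed interval for the sampling CDF
    s1e, s2e = mie_s1_s2(m, x, np.array([-1.0, 1.0]))
    pdf_ends = 0.5 * (np.abs(s1e) ** 2 + np.abs(s2e) ** 2) / norm
    grid = np.concatenate(([-1.0], nodes, [1.0]))
    pdf = np.concatenate(([pdf_ends[0]], pdf_nodes, [pdf_ends[1]]))

    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    # make pdf and cdf consistent under the trapezoid rule used for sampling
    pdf = pdf / cdf[-1]
    cdf = cdf / cdf[-1]
    cdf[0] = 0.0
    cdf[-1] = 1.0

    return PhaseFunctionTable(
        cos_theta_grid=grid,
        pdf=pdf,
        cdf=cdf,
        mean_cos=mean_cos,
        metadata={
            "wavelength_nm": spec.wavelength_nm,
            "particle_diameter_nm": spec.particle_diameter_nm,
            "host_index": spec.host_index,
            "particle_index": spec.relative_index * spec.host_index,
            "size_parameter": x,
            "relative_index": m,
            "n_grid_points": n_grid_points,
        },
    )


def sample_table(table: PhaseFunctionTable, u):
    """Inverse-CDF draw of cos theta with linear interpolation between nodes."""
    u = np.asarray(u, dtype=float)
    ct = np.interp(u, table.cdf, table.cos_theta_grid)
    return float(ct) if ct.ndim == 0 else ct


def table_to_csv(table: PhaseFunctionTable, path) -> None:
    """Export a phase-function table for external inspection."""
    arr = np.column_stack([table.cos_theta_grid, table.pdf, table.cdf])
    header = "cos_theta,pdf,cdf"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
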