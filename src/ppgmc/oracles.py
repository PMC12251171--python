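"""Closed-form references used to cross-check the transport kernel.

All oracles are pure and deterministic: Lambert-Beer transmission,
Snell refraction, the HG mean cosine, and a diffusion-theory estimate of
semi-infinite diffuse reflectance used only as an order-of-magnitude
check (the real scene, with glass, air gap and a finite cylinder,
departs from the half-space idealisation, hence the loose tolerance
applied where it is used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .scene import OpticalProperties

__all__ = [
    "beer_lambert",
    "snell_angle",
    "diffusion_reflectance",
    "hg_mean_cosine",
    "TotalInternalReflection",
    "OracleReport",
    "report_frame",
]


class TotalInternalReflection(ValueError):
    """Signals an evanescent (totally internally reflected) input."""


@dataclass(frozen=True)
class OracleReport:
    name: str
    analytic: float
    simulated: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.analytic - self.simulated) <= self.tolerance


def report_frame(reports) -> pd.DataFrame:
    rows = [
        {
            "oracle": r.name,
            "analytic": r.analytic,
            "simulated": r.simulated,
            "tolerance": r.tolerance,
            "passed": r.passed,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["oracle", "analytic", "simulated",
                                       "tolerance", "passed"])


def beer_lambert(mu_a: float, thickness: float) -> float:
    """Transmission exp(-mu_a * t) through a non-scattering slab."""
    if mu_a < 0 or thickness < 0:
        raise ValueError("mu_a and thickness must be non-negative")
    return math.exp(-mu_a * thickness)


def snell_angle(n1: float, n2: float, theta_in_deg: float) -> float:
    """Refraction angle in degrees; raises on total internal reflection."""
    s = n1 * math.sin(math.radians(theta_in_deg)) / n2
    if abs(s) > 1.0:
        raise TotalInternalReflection(
            f"sin(theta_t) = {s:.4f} beyond the critical angle"
        )
    return math.degrees(math.asin(s))


def hg_mean_cosine(g: float) -> float:
    """First moment of the Henyey-Greenstein phase function (equals g)."""
    return g


def diffusion_reflectance(props: OpticalProperties) -> float:
    """Approximate total diffuse reflectance of a semi-infinite medium.

    Classic diffusion-theory closed form parameterised by the transport
    albedo a' = mu_s' / (mu_s' + mu_a):

        R = (a'/2) * (1 + exp(-(4/3) A sqrt(3(1-a')))) * exp(-sqrt(3(1-a')))

    with the internal-reflection parameter A = (1 + r_d)/(1 - r_d),
    r_d ~= -1.440/n^2 + 0.710/n + 0.668 + 0.0636 n for the relative index
    n of the medium against its surround (A = 1 when index-matched).
    """
    if props.mu_s_reduced <= 0:
        raise ValueError("diffusion estimate needs mu_s' > 0")
    a = props.mu_s_reduced / (props.mu_s_reduced + props.mu_a)
    n = props.n
    if abs(n - 1.0) < 1e-12:
        big_a = 1.0
    else:
        rd = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        big_a = (1.0 + rd) / (1.0 - rd)
    root = math.sqrt(3.0 * (1.0 - a))
    return 0.5 * a * (1.0 + math.exp(-4.0 / 3.0 * big_a * root)) * math.exp(-root)
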