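"""Rayleigh-wave stiffness calibration for RRT arrival times.

The measurement device reports arrival times in arbitrary RRT units.  The
calibration assumes the wave is a Rayleigh surface wave on an unstressed,
incompressible, linear elastic, isotropic half-space, for which

    E = rho * v^2 * 3.284

with ``E`` the Young modulus (Pa), ``rho`` the density (kg/m^3) and ``v``
the wave speed (m/s).  Measuring three elastomers of known modulus and
density gives, per material, the wave speed, the transit time over the
2 mm transducer gap, and hence the duration of one RRT unit in
microseconds.  The average over the three reference elastomers is
approximately 0.284 us per RRT.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Rayleigh-speed factor for an unstressed incompressible isotropic solid.
RAYLEIGH_CONSTANT = 3.284

#: Separation of the emitting and receiving transducers, metres.
DEFAULT_TRANSDUCER_GAP_M = 0.002


@dataclass(frozen=True)
class CalibrationMaterial:
    """A reference elastomer of known density, modulus and mean RRT."""

    name: str
    density: float  # kg/m^3
    young_modulus: float  # Pa
    mean_rrt: float  # RRT units
    transducer_gap: float = DEFAULT_TRANSDUCER_GAP_M  # metres

    def __post_init__(self) -> None:
        for attr in ("density", "young_modulus", "mean_rrt", "transducer_gap"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


def rayleigh_speed(material: CalibrationMaterial) -> float:
    """Rayleigh wave speed in m/s: v = sqrt(E / (3.284 * rho))."""
    return (material.young_modulus / (RAYLEIGH_CONSTANT * material.density)) ** 0.5


def rrt_conversion(material: CalibrationMaterial) -> float:
    """Duration of one RRT unit in microseconds for this material.

    The wave crosses the transducer gap in ``gap / v`` seconds, which the
    device reported as ``mean_rrt`` RRT units.
    """
    transit_us = material.transducer_gap / rayleigh_speed(material) * 1e6
    return transit_us / material.mean_rrt


def stiffness_from_rrt(
    arrival_rrt: float,
    conversion_us_per_rrt: float,
    density: float,
    gap: float = DEFAULT_TRANSDUCER_GAP_M,
) -> float:
    """Young modulus (Pa) implied by an arrival time in RRT units."""
    if min(arrival_rrt, conversion_us_per_rrt, density, gap) <= 0:
        raise ValueError("all inputs must be positive")
    t_s = arrival_rrt * conversion_us_per_rrt * 1e-6
    v = gap / t_s
    return density * v**2 * RAYLEIGH_CONSTANT


def load_materials(path=None) -> list[CalibrationMaterial]:
    """Load calibration materials from CSV (bundled reference set by default).

    Columns: name, density_kg_m3, young_modulus_pa, mean_rrt.
    """
    if path is None:
        src = resources.files("skinaniso").joinpath("data/materials.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        CalibrationMaterial(
            name=row["name"],
            density=float(row["density_kg_m3"]),
            young_modulus=float(row["young_modulus_pa"]),
            mean_rrt=float(row["mean_rrt"]),
        )
        for _, row in df.iterrows()
    ]


def calibration_table(materials: list[CalibrationMaterial] | None = None) -> pd.DataFrame:
    """Per-material speeds and RRT conversions, plus their mean.

    Reproduces the reference-elastomer calibration: one row per material
    with the Rayleigh speed and microseconds per RRT; the mean conversion
    over materials is the device-level calibration constant.
    """
    materials = materials if materials is not None else load_materials()
    rows = [
        {
            "name": m.name,
            "density_kg_m3": m.density,
            "young_modulus_pa": m.young_modulus,
            "mean_rrt": m.mean_rrt,
            "rayleigh_speed_m_s": rayleigh_speed(m),
            "rrt_conversion_us": rrt_conversion(m),
        }
        for m in materials
    ]
    df = pd.DataFrame(rows)
    df.attrs["mean_conversion_us"] = float(df["rrt_conversion_us"].mean())
    return df
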