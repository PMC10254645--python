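"""Per-particle sizing, concentrations and the size detection limit.

An event's integrated counts I convert to analyte mass through the
calibrated response K = s/(Q_sam·η_neb) counts per µg:

    m = I · Q_sam · η_neb / s

and to a spherical-equivalent diameter through the sphere model

    d = (6 m / (π ρ X_NP))^(1/3)

with particle density ρ and analyte mass fraction X_NP.  The smallest
diameter distinguishable from background follows from the 3σ criterion
on the background standard deviation σ_B and the counts-per-mass
response K_ICPMS·K_M:

    LOD_size = (6 · 3 σ_B / (π ρ X_NP K_ICPMS K_M))^(1/3)
    K_ICPMS·K_M = R / (K_intr · C_M),   K_intr = η_neb · Q_sam

where R is the count rate produced by a dissolved standard of
concentration C_M.  Note the deliberate asymmetry inherited from
practice: events are *detected* at 5σ_b, but the size LOD is *reported*
at the conventional 3σ_B; both multipliers are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibrate import FlowRate, IonicCalibration, TransportEfficiency
from .detect import BaselineStats, ParticleEventRaw
from .io import AcquisitionMeta, TimeScan

__all__ = [
    "AVOGADRO",
    "ElementParams",
    "IRON",
    "GOLD_DENSITY",
    "QuantifiedEvent",
    "SampleResult",
    "event_mass",
    "mass_to_diameter",
    "diameter_to_mass",
    "number_concentration",
    "dissolved_concentration",
    "detection_efficiency_product",
    "size_lod",
    "signal_to_noise",
]

AVOGADRO = 6.02214076e23  # 1/mol, exact SI constant


@dataclass(frozen=True)
class ElementParams:
    """Element and particle constants for counts→mass→size conversion.

    density_rho: particle density, g/cm³
    mass_fraction_x: analyte fraction of particle mass, (0, 1]
    isotope_abundance_a: abundance of the monitored isotope, (0, 1]
    molar_mass_m: g/mol
    """

    density_rho: float
    mass_fraction_x: float = 1.0
    isotope_abundance_a: float = 1.0
    molar_mass_m: float = 1.0

    def __post_init__(self) -> None:
        if min(self.density_rho, self.mass_fraction_x, self.isotope_abundance_a,
               self.molar_mass_m) <= 0:
            raise ValueError("all element parameters must be > 0")
        if self.mass_fraction_x > 1 or self.isotope_abundance_a > 1:
            raise ValueError("mass fraction and abundance must be <= 1")

    @property
    def k_m(self) -> float:
        """Element factor A·N_Av/M_M: monitored atoms per gram of analyte."""
        return self.isotope_abundance_a * AVOGADRO / self.molar_mass_m


#: Metallic-iron core monitored at m/z 56 (91.7% natural abundance).
IRON = ElementParams(
    density_rho=7.87, mass_fraction_x=1.0, isotope_abundance_a=0.917,
    molar_mass_m=55.85,
)

#: Density of the 50 nm Au transport-efficiency standard, g/cm³.
GOLD_DENSITY = 19.30


@dataclass(frozen=True)
class QuantifiedEvent:
    """A detected event with its analyte mass (µg) and diameter (nm)."""

    raw: ParticleEventRaw
    mass: float
    diameter: float


@dataclass(frozen=True)
class SampleResult:
    """Per-sample summary of a single-particle run.

    Concentrations: ``number_concentration`` and ``dissolved_ug_l``
    refer to the suspension as measured; ``*_per_gram`` values fold in
    the dilution factor, extract volume and tissue mass from the
    acquisition metadata.  ``particulate_mass_ug_l`` is the summed
    particle analyte mass per litre of measured suspension.
    """

    n_events: int
    number_concentration: float  # particles / L, as measured
    number_per_gram: float  # particles / g tissue
    particulate_mass_ug_l: float  # µg / L, as measured
    particulate_mass_ng_per_gram: float  # ng / g tissue
    dissolved_ug_l: float  # µg / L, as measured
    lod_size: float  # nm
    median_diameter: float  # nm
    occupancy: float = 0.0
    coincidence_flag: bool = False

    @property
    def dissolved_fraction(self) -> float:
        """Dissolved analyte as a fraction of total (dissolved + particulate)."""
        total = self.dissolved_ug_l + self.particulate_mass_ug_l
        return self.dissolved_ug_l / total if total > 0 else 0.0


def event_mass(
    ev: ParticleEventRaw,
    cal: IonicCalibration,
    flow: FlowRate,
    eta: TransportEfficiency,
) -> float:
    """Analyte mass (µg) of one event: m = I·Q_sam·η_neb/s."""
    if cal.slope_s <= 0:
        raise ValueError("calibration slope must be > 0")
    if ev.integrated_counts < 0:
        raise ValueError("negative integrated counts")
    return ev.integrated_counts * flow.q_sam * eta.eta_neb / cal.slope_s


def mass_to_diameter(m_ug, elem: ElementParams):
    """Spherical-equivalent diameter (nm) from analyte mass (µg).

    d = (6m/(πρX))^(1/3); the 1e5 factor converts (µg, g/cm³) to nm.
    Accepts arrays; m = 0 maps to d = 0.
    """
    m = np.asarray(m_ug, dtype=float)
    if np.any(m < 0):
        raise ValueError("mass must be >= 0")
    d = (6.0 * m / (np.pi * elem.density_rho * elem.mass_fraction_x)) ** (1.0 / 3.0)
    return d * 1e5


def diameter_to_mass(d_nm, elem: ElementParams):
    """Inverse of :func:`mass_to_diameter`: analyte µg from diameter nm."""
    d = np.asarray(d_nm, dtype=float)
    return elem.density_rho * elem.mass_fraction_x * (np.pi / 6.0) * d**3 * 1e-15


def number_concentration(
    n_events: int,
    flow: FlowRate,
    eta: TransportEfficiency,
    meta: AcquisitionMeta,
) -> tuple[float, float]:
    """Particle number concentration.

    Returns ``(per_litre, per_gram)``: events divided by the effective
    sample volume η_neb·Q_sam·t gives the concentration of the measured
    suspension; per-litre then folds in the dilution factor (extract
    concentration) and per-gram additionally the extract volume over
    tissue mass.
    """
    if meta.total_time <= 0:
        raise ValueError("total_time must be > 0")
    measured = n_events / (eta.eta_neb * flow.q_sam * meta.total_time)
    per_litre = measured * meta.dilution_factor
    per_gram = per_litre * meta.extract_volume / meta.tissue_mass
    return per_litre, per_gram


def dissolved_concentration(
    stats: BaselineStats,
    cal: IonicCalibration,
    meta: AcquisitionMeta,
) -> float:
    """Dissolved analyte concentration (µg/L) of the measured suspension.

    The baseline count rate I_b/dwell_time, blank-corrected by the
    calibration intercept, divided by the slope.  Negative estimates
    (blank fluctuation) floor at zero with a warning.
    """
    if cal.slope_s <= 0:
        raise ValueError("calibration slope must be > 0")
    c = (stats.i_b / meta.dwell_time - cal.intercept) / cal.slope_s
    if c < 0:
        if c * cal.slope_s < -3 * (stats.sigma_b / meta.dwell_time):
            warnings.warn(
                "dissolved concentration below blank; flooring at 0", stacklevel=2
            )
        return 0.0
    return c


def detection_efficiency_product(r_cps: float, c_m: float, k_intr: float) -> float:
    """K_ICPMS·K_M = R/(K_intr·C_M), counts per µg of analyte.

    R: count rate (cps) for a dissolved standard of concentration
    ``c_m`` (µg/L); ``k_intr`` = η_neb·Q_sam (L/s).
    """
    if r_cps <= 0 or c_m <= 0 or k_intr <= 0:
        raise ValueError("R, C_M and K_intr must all be > 0")
    return r_cps / (k_intr * c_m)


def size_lod(
    sigma_b: float,
    elem: ElementParams,
    k_product: float,
    criterion: float = 3.0,
) -> float:
    """Size detection limit (nm): (6·3σ_B/(πρX·K_ICPMS·K_M))^(1/3).

    ``sigma_b`` is the background SD in counts on the same basis
    (per-dwell or per-event-integral) as the intended comparison;
    ``k_product`` in counts per µg.  ``criterion`` is the conventional
    3 by default.
    """
    if sigma_b <= 0 or k_product <= 0 or criterion <= 0:
        raise ValueError("sigma_b, k_product and criterion must be > 0")
    m_lod = 6.0 * criterion * sigma_b / (
        np.pi * elem.density_rho * elem.mass_fraction_x * k_product
    )
    return float(m_lod ** (1.0 / 3.0) * 1e5)


def signal_to_noise(
    analyte_response: Mapping[float, float],
    matrix_traces: Mapping[float, TimeScan],
) -> tuple[dict[float, float], float | None]:
    """Signal-to-noise per cell-gas flow and the flow that maximises it.

    ``analyte_response`` maps gas flow (mL/min) to the analyte count
    rate (cps); ``matrix_traces`` maps the same flows to particle-free
    matrix scans.  The noise δ is the SD of the matrix trace on the
    per-second basis; flows with δ = 0 are flagged with NaN and excluded
    from the argmax.
    """
    if not matrix_traces:
        raise ValueError("need at least one matrix trace")
    out: dict[float, float] = {}
    for flow, scan in matrix_traces.items():
        delta = float(scan.counts.std(ddof=1)) / scan.meta.dwell_time
        if delta == 0:
            out[flow] = float("nan")
        else:
            out[flow] = analyte_response[flow] / delta
    finite = {f: v for f, v in out.items() if np.isfinite(v)}
    best = max(finite, key=finite.get) if finite else None
    return out, best
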