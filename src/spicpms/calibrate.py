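"""Counts-to-mass calibration.

Three ingredients convert an integrated event signal (counts) into an
analyte mass: the ionic response slope ``s`` (cps per µg/L) from an
external calibration curve, the sample uptake rate ``Q_sam`` (L/s) from
pump gravimetry, and the transport (nebulisation) efficiency ``η_neb``
— the fraction of aspirated sample that actually reaches the plasma.

A dissolved standard at concentration ``C`` delivers ``C·Q_sam·η_neb``
µg of analyte per second to the plasma while producing ``s·C`` counts
per second, so the instrument's response per unit analyte mass is

    K = s / (Q_sam · η_neb)      [counts per µg]

Running a nanoparticle standard of known diameter and density (the
particle-size method) gives the mean integrated counts per particle
``Ī_ref`` for a known reference mass ``m_ref``; inverting K yields

    η_neb = m_ref · s / (Ī_ref · Q_sam)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IonicCalibration",
    "FlowRate",
    "TransportEfficiency",
    "fit_ionic_calibration",
    "measure_flow_rate",
    "transport_efficiency_particle_size",
    "counts_per_microgram",
    "sphere_mass_ug",
]

WATER_DENSITY_G_PER_ML = 1.0


@dataclass(frozen=True)
class IonicCalibration:
    """Ordinary least-squares ionic response line.

    ``slope_s`` is in cps per (µg/L); ``intercept`` in cps (the blank
    response, including any continuum instrument background).
    """

    slope_s: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class FlowRate:
    """Sample uptake rate from pump gravimetry, litres per second."""

    q_sam: float
    replicate_masses: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.q_sam <= 0:
            raise ValueError("q_sam must be > 0")

    @property
    def ml_per_min(self) -> float:
        return self.q_sam * 1e3 * 60.0


@dataclass(frozen=True)
class TransportEfficiency:
    """Nebulisation efficiency η_neb in (0, 1] and how it was obtained."""

    eta_neb: float
    method: str = "particle_size"
    reference: tuple[float, float, float] | None = None  # (d_ref nm, ρ_ref, Ī_ref)

    def __post_init__(self) -> None:
        if not 0 < self.eta_neb <= 1:
            raise ValueError(f"eta_neb must be in (0, 1], got {self.eta_neb}")


def fit_ionic_calibration(
    points: Sequence[tuple[float, float]],
    response_unit: str = "cps",
    dwell_time: float | None = None,
) -> IonicCalibration:
    """Fit the external calibration line response = s·C + b.

    ``points`` are (concentration µg/L, response) pairs.  Responses in
    counts per dwell (``response_unit="counts_per_dwell"``) are converted
    to cps via ``dwell_time`` before fitting, so the slope is always on
    the per-second basis the rest of the pipeline expects.
    """
    pts = [(float(c), float(r)) for c, r in points]
    if any(not (math.isfinite(c) and math.isfinite(r)) for c, r in pts):
        raise ValueError("non-finite calibration point")
    conc = np.array([c for c, _ in pts])
    resp = np.array([r for _, r in pts])
    if response_unit == "counts_per_dwell":
        if dwell_time is None or dwell_time <= 0:
            raise ValueError("dwell_time required to convert counts per dwell to cps")
        resp = resp / dwell_time
    elif response_unit != "cps":
        raise ValueError(f"unknown response_unit {response_unit!r}")
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    fit = stats.linregress(conc, resp)
    return IonicCalibration(
        slope_s=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        points=tuple(zip(conc.tolist(), resp.tolist())),
    )


def measure_flow_rate(replicates: Sequence[tuple[float, float]]) -> FlowRate:
    """Sample uptake rate from (grams of water, seconds) pump replicates.

    Water density is taken as 1.0 g/mL, so grams per second map directly
    to mL/s and hence L/s.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    rates = []
    for grams, seconds in replicates:
        if grams <= 0 or seconds <= 0:
            raise ValueError("replicate mass and duration must be > 0")
        rates.append((grams / WATER_DENSITY_G_PER_ML) / seconds)  # mL/s
    q_ml_per_s = float(np.mean(rates))
    return FlowRate(
        q_sam=q_ml_per_s * 1e-3,
        replicate_masses=tuple((float(g), float(s)) for g, s in replicates),
    )


def sphere_mass_ug(d_nm: float, density: float, mass_fraction: float = 1.0):
    """Analyte mass (µg) of a spherical particle of diameter ``d_nm``.

    ``density`` in g/cm³; ``mass_fraction`` is the analyte fraction of
    the particle mass (1.0 for a pure metallic core).  Accepts arrays.
    """
    d = np.asarray(d_nm, dtype=float)
    # nm³ → cm³ is 1e-21; g → µg is 1e6
    return density * mass_fraction * (np.pi / 6.0) * d**3 * 1e-15


def counts_per_microgram(cal: IonicCalibration, flow: FlowRate, eta_neb: float) -> float:
    """Instrument response per µg of analyte delivered: s/(Q_sam·η)."""
    if cal.slope_s <= 0:
        raise ValueError("calibration slope must be > 0")
    if not 0 < eta_neb <= 1:
        raise ValueError("eta_neb must be in (0, 1]")
    return cal.slope_s / (flow.q_sam * eta_neb)


def transport_efficiency_particle_size(
    ref_events,
    d_ref: float,
    rho_ref: float,
    cal: IonicCalibration,
    flow: FlowRate,
    mass_fraction: float = 1.0,
    min_events: int = 50,
    outlier_fraction: float = 0.1,
) -> TransportEfficiency:
    """Transport efficiency by the particle-size method.

    ``ref_events`` are detected events from a run of a nanoparticle
    standard of known diameter ``d_ref`` (nm) and density ``rho_ref``
    (g/cm³), e.g. 50 nm Au.  Events with integrated counts below
    ``outlier_fraction`` of the median are dropped before averaging —
    near-threshold noise events would otherwise bias Ī_ref low.
    """
    integrated = np.array([ev.integrated_counts for ev in ref_events], dtype=float)
    if integrated.size == 0:
        raise ValueError("no reference events")
    if integrated.size < min_events:
        warnings.warn(
            f"only {integrated.size} reference events (< {min_events}); "
            "transport efficiency may be imprecise",
            stacklevel=2,
        )
    med = float(np.median(integrated))
    kept = integrated[integrated >= outlier_fraction * med]
    i_ref = float(np.mean(kept))
    if cal.slope_s <= 0:
        raise ValueError("calibration slope must be > 0")
    m_ref = float(sphere_mass_ug(d_ref, rho_ref, mass_fraction))
    eta = m_ref * cal.slope_s / (i_ref * flow.q_sam)
    if not 0 < eta <= 1:
        raise ValueError(
            f"computed transport efficiency {eta:.3g} outside (0, 1]; "
            "calibration, flow rate and reference run are inconsistent"
        )
    return TransportEfficiency(
        eta_neb=eta, method="particle_size", reference=(d_ref, rho_ref, i_ref)
    )
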