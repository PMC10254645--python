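"""Synthetic time-scan generation with known ground truth.

The generator emulates the statistical structure the downstream stages
assume: particle arrivals as a Poisson process at a rate set by the
number concentration, transport efficiency and uptake rate; lognormally
distributed diameters (optionally a two-mode mixture for agglomerated
populations); each particle's ion burst spread over a few consecutive
dwells as a discretised Gaussian pulse; and a dissolved/continuum
baseline with counting (Poisson) or Gaussian noise.  Counts are rounded
to integers once, after summing pulse and baseline per dwell.

It also builds the three endpoint fixtures for nanoparticle fate in a
growth medium — stable, partial dissolution + agglomeration, and fast
dissolution — as fresh/aged trace pairs with a shared synthetic
calibration, so the whole pipeline and the transformation classifier
can be exercised without instrument data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, special

from .calibrate import FlowRate, IonicCalibration, TransportEfficiency
from .io import AcquisitionMeta, TimeScan
from .quantify import ElementParams, GOLD_DENSITY, IRON, diameter_to_mass

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ScenarioFixture",
    "SCENARIOS",
    "simulate_timescan",
    "simulate_reference_standard",
    "generate_scenario_suite",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated acquisition.

    number_concentration: particles per litre of the measured suspension
    size_median / size_gsd: lognormal diameter distribution (nm; gsd = 1
        means monodisperse)
    second_mode: optional (median nm, gsd, number fraction) second
        lognormal component, e.g. an agglomerate population
    dissolved_concentration: dissolved analyte, µg/L
    background_cps: analyte-independent continuum background (blank)
        count rate; appears in the baseline and, consistently, in the
        synthetic calibration intercept
    uptake_rate: L/s;  transport_efficiency: (0, 1]
    ionic_slope: instrument response, cps per (µg/L)
    pulse_width: full event spread in seconds (~99.7% of the ion burst);
        the discretised Gaussian uses sigma = pulse_width / 6
    baseline_noise: "poisson" or "gaussian(σ)"
    """

    number_concentration: float
    size_median: float
    size_gsd: float = 1.3
    second_mode: Optional[tuple[float, float, float]] = None
    dissolved_concentration: float = 0.0
    background_cps: float = 0.0
    uptake_rate: float = 5.833333333333333e-6  # 0.35 mL/min
    transport_efficiency: float = 0.075
    ionic_slope: float = 1e6
    pulse_width: float = 3e-4
    baseline_noise: str = "poisson"
    seed: int = 0
    coincidence_limit: float = 0.05

    def __post_init__(self) -> None:
        if self.number_concentration < 0 or self.dissolved_concentration < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 < self.transport_efficiency <= 1:
            raise ValueError("transport_efficiency must be in (0, 1]")
        if self.size_gsd < 1:
            raise ValueError("size_gsd must be >= 1")
        if self.second_mode is not None:
            _, gsd2, frac = self.second_mode
            if gsd2 < 1 or not 0 <= frac <= 1:
                raise ValueError("invalid second_mode")
        _parse_noise(self.baseline_noise)

    def expected_particles(self, meta: AcquisitionMeta) -> float:
        """Poisson mean λ = c_N · η_neb · Q_sam · t."""
        return (
            self.number_concentration
            * self.transport_efficiency
            * self.uptake_rate
            * meta.total_time
        )


@dataclass(frozen=True)
class GroundTruth:
    """Per-particle truth and the generator's mass ledger."""

    arrival_dwell: np.ndarray  # dwell index of each pulse centre
    diameters: np.ndarray  # nm
    masses: np.ndarray  # µg analyte per particle
    dissolved_ug_l: float
    expected_event_count: float  # Poisson mean λ
    particulate_ug_l: float  # Σ masses / (η_neb·Q_sam·t), as measured

    @property
    def n_particles(self) -> int:
        return int(self.diameters.size)

    @property
    def median_diameter(self) -> float:
        return float(np.median(self.diameters)) if self.diameters.size else 0.0

    @property
    def dissolved_fraction(self) -> float:
        total = self.dissolved_ug_l + self.particulate_ug_l
        return self.dissolved_ug_l / total if total > 0 else 0.0


def _parse_noise(spec: str) -> tuple[str, float]:
    if spec == "poisson":
        return "poisson", 0.0
    m = re.fullmatch(r"gaussian\(([^)]*)\)", spec)
    if m:
        sigma = float(m.group(1))
        if sigma < 0:
            raise ValueError("gaussian noise sigma must be >= 0")
        return "gaussian", sigma
    raise ValueError(f"unknown baseline_noise {spec!r}")


def _draw_diameters(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cfg.second_mode is None:
        heavy = np.zeros(n, dtype=bool)
    else:
        heavy = rng.random(n) < cfg.second_mode[2]
    d = np.empty(n)
    for mask, (median, gsd) in (
        (~heavy, (cfg.size_median, cfg.size_gsd)),
        (heavy, cfg.second_mode[:2] if cfg.second_mode else (1.0, 1.0)),
    ):
        k = int(mask.sum())
        if k:
            if gsd == 1.0:
                d[mask] = median
            else:
                d[mask] = np.exp(rng.normal(np.log(median), np.log(gsd), k))
    return d


def simulate_timescan(
    cfg: SimulationConfig,
    meta: AcquisitionMeta | None = None,
    elem: ElementParams = IRON,
) -> tuple[TimeScan, GroundTruth]:
    """Simulate one acquisition; returns the trace and its ground truth.

    Each particle of analyte mass m produces m·s/(Q_sam·η_neb) total
    counts, deposited over consecutive dwells as a discretised Gaussian
    of width ``pulse_width``; the baseline mean per dwell is
    (s·C_diss + background_cps)·dwell_time.  Identical configs (same
    seed) reproduce identical traces.  Raises in the coincidence regime
    where the expected pulse occupancy exceeds ``coincidence_limit`` —
    the physical remedy is dilution, not processing.
    """
    if meta is None:
        meta = AcquisitionMeta()
    rng = np.random.default_rng(cfg.seed)
    n_dwells = meta.n_dwells
    lam = cfg.expected_particles(meta)
    span_dwells = max(1.0, cfg.pulse_width / meta.dwell_time)
    if lam * span_dwells > cfg.coincidence_limit * n_dwells:
        raise ValueError(
            f"expected dwell occupancy {lam * span_dwells / n_dwells:.1%} exceeds "
            f"{cfg.coincidence_limit:.0%}: coincidence regime, dilute the suspension"
        )

    n_particles = int(rng.poisson(lam)) if lam > 0 else 0
    arrival_t = np.sort(rng.uniform(0.0, meta.total_time, n_particles))
    diam = _draw_diameters(cfg, n_particles, rng)
    masses = diameter_to_mass(diam, elem)
    counts_per_ug = cfg.ionic_slope / (cfg.uptake_rate * cfg.transport_efficiency)
    totals = masses * counts_per_ug

    trace = np.zeros(n_dwells)
    sigma_t = cfg.pulse_width / 6.0
    dwell = meta.dwell_time
    if sigma_t > 0:
        # keep the full ±4σ window inside the trace
        arrival_t = np.clip(arrival_t, 4 * sigma_t, meta.total_time - 4 * sigma_t)
    for t_c, tot in zip(arrival_t, totals):
        if sigma_t == 0:
            trace[min(int(t_c / dwell), n_dwells - 1)] += tot
            continue
        k_lo = max(int((t_c - 4 * sigma_t) / dwell), 0)
        k_hi = min(int((t_c + 4 * sigma_t) / dwell) + 1, n_dwells - 1)
        edges = np.arange(k_lo, k_hi + 2) * dwell
        cdf = special.ndtr((edges - t_c) / sigma_t)
        frac = np.diff(cdf)
        trace[k_lo : k_hi + 1] += tot * frac / frac.sum()

    mu_b = (cfg.ionic_slope * cfg.dissolved_concentration + cfg.background_cps) * dwell
    kind, sigma = _parse_noise(cfg.baseline_noise)
    if kind == "poisson":
        baseline = rng.poisson(mu_b, n_dwells) if mu_b > 0 else np.zeros(n_dwells)
    else:
        baseline = rng.normal(mu_b, sigma, n_dwells) if sigma > 0 else np.full(
            n_dwells, mu_b
        )
    counts = np.rint(trace + baseline).astype(np.int64)
    np.clip(counts, 0, None, out=counts)

    delivered = cfg.transport_efficiency * cfg.uptake_rate * meta.total_time
    truth = GroundTruth(
        arrival_dwell=np.minimum((arrival_t / dwell).astype(np.int64), n_dwells - 1),
        diameters=diam,
        masses=masses,
        dissolved_ug_l=cfg.dissolved_concentration,
        expected_event_count=lam,
        particulate_ug_l=float(masses.sum() / delivered) if delivered > 0 else 0.0,
    )
    return TimeScan(counts=counts, meta=meta), truth


def simulate_reference_standard(
    d_ref: float,
    rho_ref: float = GOLD_DENSITY,
    cfg: SimulationConfig | None = None,
    meta: AcquisitionMeta | None = None,
) -> tuple[TimeScan, GroundTruth]:
    """Simulate a run of a nanoparticle size standard (default 50 nm Au).

    The population is monodisperse at ``d_ref`` unless ``cfg`` asks for
    a narrow spread; the element is a pure particle of density
    ``rho_ref``.
    """
    if d_ref <= 0:
        raise ValueError("d_ref must be > 0")
    if cfg is None:
        cfg = SimulationConfig(number_concentration=1.0e7, size_median=d_ref,
                               size_gsd=1.0)
    cfg = replace(cfg, size_median=d_ref, second_mode=None)
    elem = ElementParams(density_rho=rho_ref, mass_fraction_x=1.0)
    return simulate_timescan(cfg, meta, elem)


@dataclass(frozen=True)
class ScenarioFixture:
    """A fresh/aged trace pair with the shared synthetic instrument state."""

    scenario: str
    fresh: TimeScan
    aged: TimeScan
    fresh_truth: GroundTruth
    aged_truth: GroundTruth
    calibration: IonicCalibration
    flow: FlowRate
    eta: TransportEfficiency
    element: ElementParams


SCENARIOS = ("stable", "dissolution_agglomeration", "fast_dissolution")

# Shared fixture instrument state: response slope (cps per µg/L),
# continuum blank (cps), uptake rate (L/s), transport efficiency.
_FIX_SLOPE = 1e6
_FIX_BACKGROUND = 5e5  # 50 counts per 100 µs dwell: a smooth blank
_FIX_Q = 5.833333333333333e-6
_FIX_ETA = 0.075
_FIX_EVENTS = 400.0  # target expected events per 120 s trace


def _fixture_number_concentration(meta: AcquisitionMeta, lam: float) -> float:
    return lam / (_FIX_ETA * _FIX_Q * meta.total_time)


def _agglomerate_weight(primary: float, gsd1: float, heavy: float, gsd2: float,
                        pooled_median: float) -> float:
    """Heavy-mode number fraction making the mixture median equal
    ``pooled_median``."""

    def mixture_cdf_at_target(w: float) -> float:
        f1 = special.ndtr(np.log(pooled_median / primary) / np.log(gsd1))
        f2 = special.ndtr(np.log(pooled_median / heavy) / np.log(gsd2))
        return (1 - w) * f1 + w * f2 - 0.5

    return float(optimize.brentq(mixture_cdf_at_target, 0.0, 1.0))


def generate_scenario_suite(
    scenario: str,
    seed: int,
    meta: AcquisitionMeta | None = None,
) -> ScenarioFixture:
    """Build one fresh/aged fixture for a nanoparticle-fate scenario.

    stable:
        fresh median 59 nm, aged 61 nm, negligible dissolved fraction.
    dissolution_agglomeration:
        fresh single mode at 55 nm; aged keeps a reduced primary mode
        and gains a heavy agglomerate mode such that the pooled median
        is 81 nm, with an elevated dissolved background.
    fast_dissolution:
        aged trace with only a handful of surviving particles and a
        dominant dissolved baseline.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if meta is None:
        meta = AcquisitionMeta(sample_id=f"{scenario}-{seed}")
    base = dict(
        number_concentration=_fixture_number_concentration(meta, _FIX_EVENTS),
        size_gsd=1.3,
        background_cps=_FIX_BACKGROUND,
        uptake_rate=_FIX_Q,
        transport_efficiency=_FIX_ETA,
        ionic_slope=_FIX_SLOPE,
    )
    if scenario == "stable":
        fresh_cfg = SimulationConfig(size_median=59.0, dissolved_concentration=2e-4,
                                     seed=seed * 2 + 1, **base)
        aged_cfg = SimulationConfig(size_median=61.0, dissolved_concentration=2e-4,
                                    seed=seed * 2 + 2, **base)
    elif scenario == "dissolution_agglomeration":
        w = _agglomerate_weight(55.0, 1.3, 150.0, 1.3, pooled_median=81.0)
        fresh_cfg = SimulationConfig(size_median=55.0, dissolved_concentration=2e-4,
                                     seed=seed * 2 + 1, **base)
        aged_cfg = SimulationConfig(
            size_median=55.0,
            second_mode=(150.0, 1.3, w),
            dissolved_concentration=0.03,
            seed=seed * 2 + 2,
            **base,
        )
    else:  # fast_dissolution
        fresh_cfg = SimulationConfig(size_median=55.0, dissolved_concentration=2e-4,
                                     seed=seed * 2 + 1, **base)
        aged_base = dict(base, number_concentration=_fixture_number_concentration(meta, 8.0))
        aged_cfg = SimulationConfig(size_median=55.0, dissolved_concentration=0.05,
                                    seed=seed * 2 + 2, **aged_base)

    fresh, fresh_truth = simulate_timescan(fresh_cfg, meta)
    aged, aged_truth = simulate_timescan(aged_cfg, meta)
    cal = IonicCalibration(slope_s=_FIX_SLOPE, intercept=_FIX_BACKGROUND, r_squared=1.0)
    return ScenarioFixture(
        scenario=scenario,
        fresh=fresh,
        aged=aged,
        fresh_truth=fresh_truth,
        aged_truth=aged_truth,
        calibration=cal,
        flow=FlowRate(q_sam=_FIX_Q),
        eta=TransportEfficiency(eta_neb=_FIX_ETA, method="fixture"),
        element=IRON,
    )
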