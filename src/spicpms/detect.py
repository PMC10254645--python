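"""Baseline estimation, detection threshold and particle-event extraction.

The particle/dissolved discrimination threshold is

    I_thresh = I_b + k · σ_b        (k = 5 by default)

where I_b and σ_b are the mean and standard deviation of the baseline.
Because particle pulses contaminate the raw moments, the baseline is
purged iteratively: compute mean and SD over the retained dwells,
exclude dwells above mean + k·SD, and repeat until the retained set is
stable.  Events are maximal runs of dwells strictly above the threshold
(ties fall to baseline), optionally merging runs separated by short
sub-threshold gaps — at microsecond dwells a single particle's ion
cloud spans several dwells and can dip below threshold mid-pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TimeScan

__all__ = [
    "BaselineStats",
    "ParticleEventRaw",
    "estimate_baseline",
    "compute_threshold",
    "detect_events",
    "coincidence_check",
]


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean, spread and the resulting detection threshold."""

    i_b: float
    sigma_b: float
    i_thresh: float
    n_baseline_dwells: int
    n_iterations: int
    multiplier: float = 5.0


@dataclass(frozen=True)
class ParticleEventRaw:
    """One detected particle event.

    ``integrated_counts`` is the baseline-corrected total: the sum of
    (counts − I_b) over the member dwells, so longer events receive
    proportionally larger corrections.
    """

    start_dwell: int
    n_dwells: int
    integrated_counts: float
    peak_counts: float

    @property
    def end_dwell(self) -> int:
        """One past the last member dwell."""
        return self.start_dwell + self.n_dwells


def estimate_baseline(
    scan: TimeScan,
    multiplier: float = 5.0,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> BaselineStats:
    """Iterative mean + k·SD exclusion baseline.

    Starting from all dwells, repeatedly exclude dwells above
    mean + ``multiplier``·SD of the currently retained set until the
    retained set stops changing (or its moments change by less than
    ``tol`` relative), up to ``max_iter`` passes.
    """
    counts = scan.counts.astype(float)
    if counts.size == 0:
        raise ValueError("empty scan")
    retained = np.ones(counts.size, dtype=bool)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        cutoff = mean + multiplier * sd
        new_retained = counts <= cutoff
        if not new_retained.any():
            raise ValueError("all dwells excluded; pathological trace")
        if np.array_equal(new_retained, retained):
            break
        retained = new_retained
        sub = counts[retained]
        new_mean = float(sub.mean())
        new_sd = float(sub.std(ddof=1)) if sub.size > 1 else 0.0
        converged = abs(new_mean - mean) <= tol * max(abs(mean), 1e-300) and abs(
            new_sd - sd
        ) <= tol * max(sd, 1e-300)
        mean, sd = new_mean, new_sd
        if converged:
            break
    return BaselineStats(
        i_b=mean,
        sigma_b=sd,
        i_thresh=mean + multiplier * sd,
        n_baseline_dwells=int(retained.sum()),
        n_iterations=n_iter,
        multiplier=multiplier,
    )


def compute_threshold(stats: BaselineStats, multiplier: float | None = None) -> float:
    """Detection threshold I_b + k·σ_b (k defaults to the stats' own)."""
    k = stats.multiplier if multiplier is None else multiplier
    return stats.i_b + k * stats.sigma_b


def detect_events(
    scan: TimeScan,
    stats: BaselineStats,
    gap_tolerance: int = 0,
) -> list[ParticleEventRaw]:
    """Extract particle events from a scan given its baseline stats.

    Maximal runs of dwells with counts strictly above I_thresh become
    one event each; runs separated by at most ``gap_tolerance``
    sub-threshold dwells are merged (gap dwells become member dwells).
    Events are sorted by start dwell.
    """
    counts = scan.counts.astype(float)
    above = counts > stats.i_thresh
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_ends = np.r_[idx[breaks], idx[-1]] + 1  # exclusive
    # merge runs separated by <= gap_tolerance sub-threshold dwells
    merged: list[tuple[int, int]] = []
    for s, e in zip(run_starts.tolist(), run_ends.tolist()):
        if merged and s - merged[-1][1] <= gap_tolerance:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        seg = counts[s:e]
        events.append(
            ParticleEventRaw(
                start_dwell=int(s),
                n_dwells=int(e - s),
                integrated_counts=float(seg.sum() - (e - s) * stats.i_b),
                peak_counts=float(seg.max()),
            )
        )
    return events


def coincidence_check(
    events: list[ParticleEventRaw],
    scan: TimeScan,
    limit: float = 0.05,
) -> tuple[float, bool]:
    """Fraction of dwells occupied by events, and whether it exceeds
    ``limit`` — above a few percent occupancy, multi-particle events
    become likely and the suspension should be diluted further."""
    occupied = sum(ev.n_dwells for ev in events)
    fraction = occupied / scan.n_dwells
    return fraction, fraction > limit
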