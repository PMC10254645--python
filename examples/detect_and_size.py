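"""Simulate one acquisition and reduce it to a sample result.

Generates a 120 s trace (100 µs dwells) of ~400 iron nanoparticle
events at a 59 nm median over a 2 µg/L dissolved-iron baseline, then
runs baseline estimation, 5σ event detection, counts→mass→diameter
conversion and concentration reporting.
"""

from spicpms import (
    AcquisitionMeta,
    FlowRate,
    IonicCalibration,
    SimulationConfig,
    TransportEfficiency,
    process_timescan,
    simulate_timescan,
)

Q_SAM = 0.35e-3 / 60.0  # 0.35 mL/min uptake, L/s
ETA = 0.075  # transport efficiency

meta = AcquisitionMeta()  # 120 s at 100 µs → 1.2e6 dwells
cfg = SimulationConfig(
    number_concentration=400 / (ETA * Q_SAM * meta.total_time),
    size_median=59.0,
    size_gsd=1.3,
    dissolved_concentration=2.0,
    seed=42,
)
scan, truth = simulate_timescan(cfg, meta)

cal = IonicCalibration(slope_s=1e6, intercept=0.0, r_squared=1.0)
out = process_timescan(scan, cal, FlowRate(q_sam=Q_SAM), TransportEfficiency(ETA))
r = out.result

print(f"simulated particles        : {truth.n_particles}")
print(f"baseline I_b, sigma_b      : {out.baseline.i_b:.2f}, {out.baseline.sigma_b:.2f} counts/dwell")
print(f"threshold I_b + 5 sigma_b  : {out.baseline.i_thresh:.2f} counts/dwell")
print(f"detected events            : {r.n_events}")
print(f"median diameter            : {r.median_diameter:.1f} nm (true {truth.median_diameter:.1f})")
print(f"number concentration       : {r.number_concentration:.3g} particles/L")
print(f"dissolved iron             : {r.dissolved_ug_l:.3f} ug/L (true {truth.dissolved_ug_l})")
print(f"size detection limit       : {r.lod_size:.1f} nm")
# The detector recovers the simulated population: the median and the
# dissolved baseline should match their ground-truth values to a few
# percent, and every reported event maps one-to-one onto a particle.
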