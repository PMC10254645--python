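# Methods

## Signal model

A single-particle ICP-MS acquisition is modelled as a counts-per-dwell
trace of length `round(total_time/dwell_time)` (default 120 s at
100 µs → 1.2×10⁶ dwells). Two components add per dwell:

- **Baseline.** Dissolved analyte at concentration `C_diss` (µg/L)
  plus an analyte-independent continuum background `background_cps`
  give a mean of `(s·C_diss + background_cps)·t_dwell` counts per
  dwell, where `s` is the ionic response slope in cps per (µg/L).
  Noise is Poisson by default (counting statistics); a Gaussian option
  with chosen σ exists so the 5σ false-positive rate can be checked
  against the analytic `P(Z>5) ≈ 2.9×10⁻⁷` per dwell.
- **Particles.** Arrivals are a Poisson process with mean
  `λ = c_N·η_neb·Q_sam·t_total`. Each particle's diameter is drawn
  lognormal (median, geometric SD), optionally from a two-component
  mixture; its analyte mass follows the sphere model
  `m = ρ·X_NP·(π/6)d³` and its total counts are `m·s/(Q_sam·η_neb)`,
  spread over consecutive dwells as a discretised Gaussian whose ±3σ
  width is `pulse_width` (default 300 µs, i.e. ion clouds span ~3
  dwells at 100 µs — the characteristic microsecond-dwell split-event
  regime). Counts are rounded to integers once, after summing pulse
  and baseline.

The generator refuses configurations whose expected pulse occupancy
exceeds 5% of dwells: that is the coincidence regime, and the physical
remedy (dilution) cannot be emulated by processing. It keeps a full
ledger (per-particle arrival, diameter, mass; dissolved concentration;
`Σm/(η_neb·Q_sam·t)` as the particulate mass concentration), which is
what all closed-loop tests compare against.

What the generator does **not** emulate: pulse-shape variability and
tailing, detector dead time, flicker (1/f) noise, spectral
interferences, matrix effects on transport, and time-correlated
baseline drift. Passing closed-loop tests therefore demonstrates the
correctness of the reduction arithmetic and its statistical behaviour
under the assumed model, not robustness to every instrumental
pathology of real traces.

## Baseline and detection

The detection threshold is `I_thresh = I_b + 5σ_b`. Since particle
pulses contaminate raw moments, `I_b, σ_b` are estimated by iterating:
compute mean and SD over retained dwells, drop dwells above
mean + 5·SD, repeat to a fixed point (≤20 passes). The lowest dwells
can never be excluded, so the loop always terminates on a non-empty
baseline. The multiplier is configurable; 5 balances false positives
(~0.34 expected per 1.2×10⁶ Gaussian dwells) against sensitivity.

Events are maximal runs of dwells strictly above threshold (a tie
falls to baseline, deterministically). Runs separated by at most
`gap_tolerance` sub-threshold dwells merge into one event
(default 0; useful when low-intensity Gaussian pulses dip below
threshold mid-event). Integrated counts subtract `I_b` per member
dwell, so longer events get proportionally larger corrections. A
trailing pulse fraction below threshold at the event edges is lost to
integration; with the default 3-dwell pulse this costs well under 1%
of counts and is the dominant (small) negative bias in recovered
masses. Occupancy above 5% of dwells raises a coincidence flag —
events are flagged, never deconvolved.

## Calibration chain

- **Uptake rate.** `Q_sam` = mean(mass/duration) over pump-gravimetry
  replicates, with water at 1.0 g/mL (0.70 g over 120 s ↔
  0.35 mL/min).
- **Ionic curve.** Ordinary least squares on (concentration µg/L,
  response cps); responses supplied per dwell are converted to cps
  first. The intercept doubles as the blank correction for the
  dissolved concentration, which makes a continuum background cancel
  exactly when calibration and sample share it.
- **Transport efficiency (particle-size method).** A dissolved
  standard delivers `C·Q_sam·η_neb` µg/s for `s·C` cps, so the
  response per delivered µg is `K = s/(Q_sam·η_neb)`. A nanoparticle
  standard of known mass `m_ref` (50 nm Au, 19.30 g/cm³ →
  1.263×10⁻⁹ µg) yields `η_neb = m_ref·s/(Ī_ref·Q_sam)` from the mean
  integrated counts per reference event. Events below 10% of the
  median integrated counts are excluded from `Ī_ref`: they are
  near-threshold noise, not reference particles. Results outside
  (0, 1] raise an error (inconsistent calibration).

## Quantification

Mass: `m = I·Q_sam·η_neb/s`. Diameter: `d = (6m/(πρX_NP))^{1/3}` with
Fe⁰ defaults ρ = 7.87 g/cm³, X_NP = 1 (an oxidised shell would lower
X_NP; both are overridable). Number concentration:
`n_events/(η_neb·Q_sam·t)`, scaled by the dilution factor for the
extract and by extract volume / tissue mass for per-gram reporting
(defaults 8.5 mL and 0.015 g). Dissolved:
`(I_b/t_dwell − intercept)/s`, floored at 0.

**Size LOD.** `LOD_size = (6·3σ_B/(πρX_NP·K_ICPMS·K_M))^{1/3}` with
the response product measured as `R/(K_intr·C_M)`. Two deliberate
conventions are surfaced rather than hidden: (i) detection uses 5σ
while the LOD uses the conventional 3σ — both multipliers are
configurable; (ii) σ_B is taken on the event-integral basis (per-dwell
σ_b × √pulse-dwells), since an event integrates several baseline
dwells. `K_M = A·N_Av/M_M` is exposed separately so `K_ICPMS` can be
factored out if wanted. The pipeline never needs the factorisation:
only the product enters the LOD.

**Gas-flow selection.** For each cell-gas flow, S/N = analyte cps /
δ, with δ the SD of a particle-free matrix trace on the per-second
basis; zero-δ flows are flagged NaN and excluded from the argmax.

## Distribution analysis and fate classification

Median and geometric SD are the MLE on log-diameters (binning-free;
the Freedman–Diaconis histogram is kept for plots only). Agglomerate
modes: 1-D Gaussian mixture on log-diameters, k ∈ {1, 2}, EM with 10
seeded restarts, BIC selection; below 50 events the fit is refused
(k = 1 with a note) because a second mode cannot be established from a
handful of particles.

The fresh-vs-aged classifier fires independent rules (all thresholds
configurable):

- **agglomeration** — aged mixture selects k = 2 with a heavy mode
  carrying ≥10% of particles at ≥1.5× the *fresh* median, or the aged
  median exceeds the fresh by >15%. Anchoring the separation on the
  fresh median matters: concentric two-component splits of a unimodal
  population, and isolated near-threshold noise components, both
  otherwise masquerade as "second modes". Physically, even a dimer
  sits at 2^{1/3} ≈ 1.26× the primary diameter, so 1.5× demands a
  genuine agglomerate population.
- **partial_dissolution** — dissolved fraction of total analyte rises
  by >10 percentage points, or the event-count ratio at matched
  dilution falls below 0.7.
- **fast_dissolution** — aged events <10% of fresh *and* dissolved
  fraction >50%.
- **stable** — none fire. Size-based rules additionally require ≥50
  aged events; a fast-dissolution trace with ~10 surviving particles
  must not earn size verdicts from a 10-particle "median".

Group comparisons use classical one-way ANOVA at α = 0.05, with F = 0
returned when all group means coincide (scipy produces NaN on
zero-variance input).

## Fixture and default choices

The fate fixtures encode the three endpoint scenarios as fresh/aged
trace pairs at ~400 expected events per 120 s trace (comfortably above
the ≥300-event practice for a stable median), uptake 0.35 mL/min,
η_neb = 7.5%, slope 10⁶ cps/(µg/L), and a 5×10⁵ cps continuum blank
(50 counts/dwell) shared by trace and calibration intercept. The blank
keeps the baseline in the smooth-Poisson regime where mean + 5·SD is a
meaningful threshold; a near-zero discrete baseline (0–1 counts per
dwell) breaks any Gaussian-moment threshold and is a genuinely
different detection problem (Poisson critical values) outside this
package's scope.

- *stable*: medians 59 → 61 nm (gsd 1.3), dissolved fraction ~2%.
- *dissolution_agglomeration*: 55 nm single mode → reduced primary
  mode plus a 150 nm agglomerate mode with the weight solved
  numerically so the pooled median is 81 nm, dissolved fraction ~30%.
- *fast_dissolution*: aged trace at λ = 8 surviving particles with a
  dominant dissolved baseline (fraction >99%).

These endpoints are fixtures, not kinetics: no dissolution or
agglomeration rate model is implied.

## Numerical notes and limitations

- All internal units are canonical (s, L, g, µg, nm, counts, cps);
  conversion happens only at I/O boundaries.
- Test and validation problem sizes — 100 false-positive traces, 20
  recovery runs, 50 efficiency runs, 30 fixtures, all at the full
  1.2×10⁶-dwell trace length — were chosen so the whole suite
  completes in well under a minute while keeping every statistical
  tolerance at ≥3σ headroom.
- Overlapping particles are merged into single events (flagged via
  occupancy, not resolved), so number concentration biases low and
  per-event mass high as occupancy grows; keep occupancy ≲1%.
- Events below the size LOD are reported, not censored; users studying
  populations straddling the LOD should filter explicitly and expect
  the usual left-truncation bias either way.
- The dissolved-concentration estimate inherits any mismatch between
  the calibration blank and the sample's true continuum background.
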