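# Methods

This note documents the models, conventions and numerical choices behind
petdosim, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic data do and do not establish.

## Physics

All internal times are minutes; residence times are reported in hours
(MBq·h/MBq). The default radionuclide is ¹⁸F with half-life 109.77 min,
decay constant λ = ln 2/109.77 ≈ 6.315·10⁻³ min⁻¹ and mean lifetime
1/λ = 2.640 h — the residence-time budget of activity that never leaves
the body. Other nuclides can be supplied through `PhysicsConstants`.

## Synthetic subjects

The simulator exists so that the estimation chain can be validated against
known ground truth. Each organ follows a single-compartment uptake–washout
law times physical decay:

F(t) = f₀ · (1 − e^(−k_up·t)) · e^(−k_bio·t) · e^(−λ·t),

the simplest form that reproduces rapid early uptake (e.g. hepatic) with
slow elimination and that admits the closed-form residence time
τ = f₀·[1/(λ+k_bio) − 1/(λ+k_bio+k_up)] used as the oracle in tests.

Parameters that matter, with defaults:

- **f₀** (dimensionless peak fractional uptake): per organ, fed and fasted
  sets; liver 0.13 fed vs 0.10 fasted (hepatic uptake is higher fed),
  muscle 0.22/0.24, kidneys 0.030/0.027, the rest small. Σf₀ plus the
  urinary fraction must not exceed 1 (mass balance; enforced).
- **k_up** (min⁻¹): 0.02–0.2 by organ; vascular/renal organs fast, muscle
  and bone slow.
- **k_bio** (min⁻¹): ≤ 5·10⁻⁴ (muscle 3·10⁻⁴, cortical bone 2·10⁻⁴),
  i.e. biological clearance half-times ≥ ~23 h. This encodes the observed
  behaviour of the tracer — organ radioactivity low and stable within
  60 min, elimination dominated by urinary excretion — and keeps the
  residence-time estimator's documented bias budget (below) under control.
- **urinary_fraction** 0.30 and **k_renal** 0.01 min⁻¹: urine is the
  dominant elimination route; bladder biological content accumulates as
  u·(1−e^(−k_renal·t)), is multiplied by e^(−λt) for the measured
  fraction, and drops to a residual (default 0.2 of content and volume,
  keeping concentration continuous) at the mid-protocol void.
- **metabolite_rate**: parent→metabolite conversion in plasma, calibrated
  so the parent fraction e^(−rate·120) equals 94.4% (fed) and 95.9%
  (fasted) at 120 min, matching the study's dietary-group means.
- **Injected activity** 159.48 MBq (the cohort mean administered activity).

The acquisition model follows the published six-pass protocol: per-bed
durations 1, 2, 5, 5, 7 and 7 min over six beds (vertex to mid-thigh,
caudocranial), scans starting at 6, 14, 30, 64, 115 and 160 min, with the
void placed midway through the break after the fourth pass. The published
protocol gives per-bed durations but no per-organ timestamps; the declared
convention here is sample time = scan start + (bed index of the organ
centroid) × minutes-per-bed, with bed order set by scan direction. This is
a modelling convention, not a measured quantity.

Measurement noise is multiplicative lognormal with unit mean and specified
CV on ROI concentrations and bladder totals (standard for PET ROI means),
and Poisson on chromatogram counts. Chromatograms are two Gaussian peaks
(parent at 9 min, metabolite at 4 min, σ = 0.15 min) on a flat 50-cpm
baseline over a 20-min run; peak identity is a retention-window label only.

What the simulator does **not** emulate: image reconstruction, scatter or
attenuation artefacts, partial-volume effects, ROI-placement error (label
masks are exact, mirroring single-investigator outlining), inter-subject
kinetic variability (subjects differ only by noise realisation), and
inter-organ redistribution. Passing recovery tests therefore demonstrates
correctness of the estimation chain under the stated noise model, not
robustness to segmentation or reconstruction error in real data.

## Residence-time estimation

The chain mirrors the study's analysis: samples are decay-corrected to the
midpoint of their whole-body scan (within-scan only — curves remain
non-decay-corrected between scans, because τ counts physical
disintegrations); concentration × reference-man organ volume / injected
activity gives fractional uptake; trapezoidal integration plus a decay-only
tail F_last/λ gives τ in hours.

Numerical and design choices:

- **t = 0 segment**: activity is zero at injection, so the default
  prepends (0, 0) and integrates the linear rise to the first sample;
  `flat_back_extrapolation` is available for organs whose uptake is
  already complete by the first scan.
- **Decay-only tail bias**: the tail assumes radioactive decay is the only
  change after the last scan (~181 min). If an organ actually clears
  biologically at rate k_bio, the tail overestimates its integral by the
  factor (λ+k_bio)/λ. The package's own bias analysis: the relative τ
  error from this simplification is ≈ 2–4% at k_bio = 5·10⁻⁴ min⁻¹ and
  grows to ~10% at 4·10⁻³ and ~20% at 10⁻². That budget is why the
  default simulated organs clear slowly; for fast-clearing tracers the
  tail assumption, not the code, is the limiting approximation.
- **Bladder**: integrated by direct trapezoid on measured totals with *no*
  decay tail — bladder radioactivity keeps rising late in the protocol, so
  a decay-only tail misrepresents filling. The dynamic voiding model in
  the dosimetry module is the principled alternative for dose scenarios.
  Bladder fractional uptake uses measured total activity divided by
  injected activity; the total divided by the reference bladder volume
  (200 mL) is retained as the "standard sized bladder" nominal
  concentration for reporting only.
- **Remainder**: two routes. With a whole-body curve,
  τ_rem = τ(whole body) − Σ organ τ. Without one (the default for
  simulated subjects), activity balance: τ_rem = 1/λ − τ_excreted − Σ τ,
  where τ_excreted = F_voided/λ is the disintegration equivalent of voided
  urine, estimated from the bladder samples bracketing the void (each
  decayed to the void time; refill between the samples makes this a slight
  underestimate, conservatively inflating the remainder). Negative
  remainders are floored at zero with a warning.
- **Superunity fractions** (possible with noise) are clipped to 1 with a
  warning, never silently.
- Degenerate inputs: a single sample yields the tail-only closed form
  F/λ; unsorted times and duplicate (organ, scan) pairs are errors;
  missing samples are flagged on the curve, not dropped.

## Dose engine

Absorbed doses are the MIRD matrix–vector product D = S·τ with per-source
contributions retained for audit; the "Remainder" maps to the
"Rest of body" source. S-matrices are user-supplied CSVs (targets ×
sources plus a mass row) validated for non-negativity, row-wise self-dose
dominance, and complete masses. Real phantom S-value tables (e.g.
Cristy–Eckerman) are third-party data and are **not** shipped; the
packaged `synthetic_smatrix` deposits the mean ¹⁸F β energy
(0.2498 MeV/decay) locally, S[o,o] = 3.6·10⁹·E·1.602·10⁻¹³/m, with a
photon cross-dose heuristic photon_fraction·k·Δγ/(m_t+m_s). It is
deterministic and unit-consistent but is a test fixture, not a transport
calculation — doses computed from it are self-consistent simulation
outputs only.

The dynamic bladder model integrates content A(t) = b(t)·e^(−λt) under
continuous renal inflow with the content reset to a residual at each
multiple of the voiding interval (default 2 h, complete voiding), over 20
half-lives with a 0.02-min trapezoid grid (relative quadrature error
~10⁻⁴ against the piecewise closed forms). k_renal = ∞ gives the
instantaneous-transfer limit used as a closed-form oracle,
τ = (1−e^(−λT_v))/λ = 1.402 h for a single 2-h void.

## Effective dose (ICRP-60)

Hard-coded 1990 weighting factors (checked to sum to 1), radiation
weighting 1 for photons/β so mGy/MBq maps to mSv/MBq. Conventions, chosen
to match the behaviour of the dose software generation the study used, all
overridable:

- colon H = 0.57·H(ULI) + 0.43·H(LLI); ULI is therefore excluded from the
  remainder list;
- oesophagus surrogate = thymus, falling back to the remainder mean when
  no thymus dose exists;
- skin and bone-surface doses fall back to the printed "Cortical bone"
  row (bone surface) or the remainder mean (skin) when absent;
- remainder = reference-mass-weighted mean over adrenals, brain, small
  intestine, kidneys, muscle, pancreas, spleen, thymus, uterus (those
  present), with the ICRP-60 splitting rule (0.025 to the organ, 0.025 to
  the rest) when one remainder organ exceeds every named tissue;
- gonads use the sex-appropriate organ; for a mixed-cohort dose table with
  both gonad doses and no sex specified, their arithmetic mean. This was a
  genuinely open choice (a hermaphrodite-phantom table has both); the mean
  is symmetric and bounded by either single-sex choice.

Applied to the packaged published 22-organ dose table, these rules give
0.0147 mSv/MBq against the published 0.0154 ± 0.0010; the residual sits in
surrogate-rule differences (thymus/oesophagus, skin) that the original
phantom software resolves with internal organ doses not printed in the
published table.

## Group statistics

Residence times and doses are averaged arithmetically with SD across
subjects (grouping by sex, diet, or all); sex-specific organs average only
over the relevant sex. Cohort dose reports compute organ doses and the
headline ED from the mean-τ table and the SD from per-subject EDs.

## Problem sizes

The test suite and the acceptance script run cohorts of 12–24 simulated
subjects at 5% ROI noise with 10⁶-count chromatograms, and voxel phantoms
of 8×8×96 voxels — sizes chosen so the whole chain (including Monte-Carlo
recovery checks with 100–200 replicates) completes in seconds while
leaving the statistical checks well-powered.

## Known limitations

- The within-scan decay correction assumes biology is frozen inside a
  scan; organs imaged far from the scan midpoint in fast-uptake phases
  (e.g. the brain during the first 1-min/bed pass) carry a small residual
  bias (~4% on τ in the recovery tests).
- The remainder's excreted-disintegration estimate ignores urine produced
  between the bracketing samples (conservative, see above).
- No compartmental fitting of TACs is provided: the workflow integrates
  measured curves, it does not model them.
- Voxel phantoms are rectangular-block abstractions for testing ROI
  quantification, not anthropomorphic geometry; no reconstruction, DICOM,
  or partial-volume handling.
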