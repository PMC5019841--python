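# Methods

## Scope and model overview

`mapk-rewire` analyses engineered kinase–substrate circuits in which a
MAPK (yeast Fus3, or a constitutively active MEK1–ERK2 fusion) is
retargeted — via modular interaction domains and a phosphodegron — to
direct the SCF/Cdc4-mediated degradation of a substrate, typically a YFP
reporter read out by flow cytometry. The package covers four layers:

1. a **synthetic event generator** that produces cytometry-like data with
   the statistical structure the processing assumes;
2. the **event-processing chain** (dialect cleaning, optional anomaly
   gating, size normalization, population summaries);
3. two **steady-state dose-response models** — the Hill amplifier
   `Y(x) = A + Bxⁿ/(1 + Cxⁿ)` and the incoherent-feed-forward band-pass
   `Y(x) = A + [Bxⁿ/(1 + Cxⁿ)]·(1 + Ex)/(1 + Dx)` — with shared-parameter
   fitting and bootstrap uncertainty;
4. a **mechanistic kinetic model** of retargeted degradation with
   scenario switches for every control and variant strain class.

## Synthetic data generator

The generator emulates one cytometer read: `n_events` (default 10,000)
events with

- cell size (FSC-A) ~ log-normal, parameterized by its median (default
  10⁵ instrument units) and linear-scale CV (default 0.4). Log-normal is
  the natural choice for cytometric size/intensity data: strictly
  positive and right-skewed. The CV is converted internally to log-space
  sigma via σ² = ln(1 + CV²);
- reporter concentration ~ log-normal (median 0.02 fluorescence units per
  FSC unit, CV 0.25), scaled by a dose- or time-dependent response scale;
- fluorescence = size × concentration + autofluorescence (default 50) +
  multiplicative Gaussian measurement noise (default SD 1% of signal; no
  instrument noise model is published for these machines, so this is a
  deliberate free parameter);
- instrument dialects: *accuri* clips fluorescence at 0 (zero floor);
  *vyb* subtracts a baseline (default 30 units), producing the negative
  values the cleaning step later offsets away;
- acquisition times uniform over a 60 s read, to support anomaly-gating
  tests.

Because fluorescence is size × concentration, fluorescence and size are
strongly correlated — the correlation that FSC normalization removes.
The observed R² rises with the size-CV/concentration-CV ratio; the
defaults above give R² ≈ 0.8. The published figures show this
correlation only graphically, so the generator defaults are realistic
free parameters, not calibrated constants.

Dose series apply a response-model scale `model(d)/model(0)`
(normalization to the untreated condition); time courses take the scale
from the kinetic model's total-reporter trajectory. Per-dose and
per-time random streams are spawned deterministically from the spec seed
and are independent of the response model, so two models that coincide
numerically produce identical event tables.

What the generator does **not** emulate: doublets and debris,
live/dead or singlet gating, spectral spillover/compensation, day
effects, instrument drift. Tests passing on synthetic data therefore
validate the *procedures* (normalization, fitting, classification), not
robustness to those real-data artifacts.

## Event processing

- **Cleaning** (per instrument dialect): Accuri zeroes → 1, so later log
  transforms are defined; VYB values are shifted by |batch minimum| + 1.
  The VYB offset is computed per acquisition batch ("that day" in
  practice); pass the other tables of the batch so the offset is shared.
  The rule is applied to every measurement column (including FSC-A),
  which also guarantees positive FSC for normalization.
- **Anomaly gating** is off by default (the original procedure was
  visual inspection). When enabled, an event is removed if its FSC-A
  deviates from the sliding 5 s-window median by more than 5 robust SDs
  (1.4826·MAD). A window longer than the read collapses to one global
  window with a logged warning.
- **Size normalization** divides each event's fluorescence by its FSC-A,
  removing the size component of fluorescence variance (typically a
  60–80% CV reduction at the generator defaults; the exact value depends
  on the size/concentration CV ratio).
- **Summaries**: median, IQR and CV per population. Quantiles use linear
  interpolation (type 7); CV = sd/mean on the linear scale (the scale is
  configurable in principle; linear is the documented default since the
  original choice is unstated). Values are sorted before reduction so
  summaries are exactly permutation-invariant.
- **Fold change** is oriented untreated/treated, so degradation gives
  values > 1 ("x-fold drop"); the log10 companion value is returned too.
  Note that an additive autofluorescence floor compresses observed
  fluorescence fold changes relative to the underlying concentration
  ratio (e.g. a 3.7× concentration drop reads as ≈ 3.5× at the default
  floor).

## Dose-response models and metrics

`A` is baseline signal, `B/C` the induced span, `n` the apparent Hill
coefficient, and `D`, `E` the saturation and residual coefficients of
the degradation (inhibitory) arm. Design choices:

- The band-pass factor `(1+Ex)/(1+Dx)` multiplies only the induced term,
  not `A`: baseline autofluorescence is not acted on by the degradation
  arm. The published equation is typeset ambiguously; the alternative
  grouping is available via `apply_factor_to_baseline=True`.
- `percent_reduction` defaults to comparing induced spans `B/C` rather
  than `A + B/C` — background signal should not count as pathway
  activation. Both variants are exposed.
- `bandpass_peak` locates the interior maximum by scanning the log-dose
  derivative of the induced term for a sign change on a 4000-point
  log-grid over 10⁻⁶–10⁶ µM, polishing with a bracketed root solve, and
  confirming by local refinement. `D ≤ E` short-circuits to "no peak"
  (the factor is then non-decreasing and the response monotone).
- `classify_response` labels a sampled curve *bandpass* when an interior
  point exceeds both endpoints by more than `rel_tol` (default 5%) of
  the curve scale, *amplifier* when the final point is maximal and
  exceeds baseline by the same margin, else *flat*.

Doses are µM throughout (the experimental pheromone range is
0.1–10 µM).

## Fitting

Fits minimize squared residuals of the model against per-dose medians
(as plotted in dose-response figures), optionally weighted by 1/IQR
width; the loss is unweighted by default since the original choice is
unstated. Bounds: A, B ≥ 0; C > 0; 0 < n ≤ 10 (preventing runaway
cooperativity on sparse grids); D, E ≥ 0. A deterministic multistart
grid (A from the curve minimum, B/C from its span, C ∈ {0.1, 1, 10},
n ∈ {1, 2, 4}, (D, E) over four corner combinations) makes results
reproducible; the best-of-grid optimum is reported with an honest
convergence flag. Flat curves are flagged unidentifiable instead of
silently "fit".

Joint fits concatenate residuals across conditions and tie any subset of
{A, B, C, n} via parameter expressions; sharing {C} between a feedback
curve and its control reproduces the shared-saturation fitting scheme.
The nested-model inequality (rss(shared) ≥ rss(free)) is asserted in
tests.

Normalization of a curve to its untreated (zero-dose) median is a
pipeline-level step rather than a default inside `fit_iffl`, because a
curve with true baseline A = 0 has no usable zero-dose divisor; the
`normalize_to_untreated` flag is available when the baseline is
positive.

Bootstrap uncertainty resamples events with replacement within each
dose, recomputes medians, and refits; replicate refits start from the
base estimate (bootstrap perturbations are small, so the multistart grid
is unnecessary there). Percentile 2.5/97.5 intervals are reported, with
refit failures counted and an error raised above a 20% failure rate.

## Kinetic model

States: active kinase K\*, unphosphorylated substrate S, phospho-tagged
substrate Sp (plus an explicit kinase–substrate complex in
explicit-binding mode). Structure:

- Kinase activation: dK\*/dt = k_act·occ_α·(K_tot − K\*) − k_inact·K\*,
  with receptor occupancy occ_α = α/(K_α + α), K_α = 1 µM (no upstream
  dose-transfer function is published; a simple binding isotherm is the
  minimal choice). A constitutively active kinase fusion pins
  K\* = K_tot.
- Binding is quasi-steady-state occupancy by default (bound fraction
  1/(1 + K_bind/K_tot), reducing stiffness); the ABA-inducible
  dimerization pair multiplies it by Hill-type ABA occupancy
  (K_aba = 1 µM, n_aba = 2, so the response turns on near 1 µM ABA);
  mismatched domains give zero; the swapped-orientation construct is
  scaled by an efficiency factor of 0.5 (a calibration default motivated
  by the roughly halved fold change of the flipped-domain strain).
  Explicit mass-action binding is available for conservation tests.
- Phosphorylation rate in complex: k_phos·min(m, m_sat) with m_sat = 3 —
  the simplest form consistent with the observed plateau in degradation
  rate beyond three degrons; a smooth Michaelis-type alternative sits
  behind `smooth_saturation`.
- Sp is degraded at k_deg (SCF/Cdc4) and dephosphorylated at k_deph;
  everything dilutes at k_dil = ln2/90 ≈ 0.0077 min⁻¹ (a 90-min doubling
  time).
- A phospho-independent basal degradation arm k_basal_deg·min(m, 5)
  models the lowered steady-state expression of multi-degron reporters.
  Its default is 0: with a nonzero default, the dead-kinase,
  broken-degron and mismatched-domain controls could not all be exactly
  equivalent to "no degradation" (the broken degron would have to gate
  the basal arm too, breaking the three-way equivalence). The arm is
  fully functional when set positive.
- The pFUS1-driven reporter mode makes synthesis pathway-dependent:
  k_syn·(basal + (1−basal)·a²/(K_txn² + a²)) with a = K\*/K_tot,
  basal leak 5%, K_txn = 0.2. Transcription then saturates at lower
  pheromone doses than the (linear-in-K\*) degradation arm, which is the
  mechanistic origin of the band-pass: output rises while transcription
  grows, then falls as degradation keeps accelerating.

No rate constants are published for this system; all defaults are
calibration choices. k_phos = 0.0495 min⁻¹ was set once so that the
fully functional constitutive strain at 10 µM pheromone loses ≈ 3.7-fold
of its reporter over 3 h — the reference behaviour of the
functional-degron strain — and was not revisited.

Competition for shared machinery is modeled with conserved pools: a
second kinase copy doubles the demand on the upstream MAPKK pool
(activation scaled by cap/(cap + demand)); a second substrate copy
shares the SCF pool (per-molecule degradation scaled by
cap/(cap + ΣSp)). Infinite capacities (the default) recover the
no-competition limit exactly.

Integration uses a stiff-capable implicit method (BDF) at rtol 10⁻⁸,
atol 10⁻¹⁰; steady states are roots of the right-hand side seeded by
long-time integration and verified by |dx/dt| < 10⁻⁹ and agreement with
t = 10⁴ min integration. Tiny negative integrator dust is clipped to
zero in reported trajectories.

Out of mechanistic scope: ubiquitin-chain length, nuclear/cytoplasmic
compartments, scaffold assembly, and upstream feedback on cascade
kinetics (handled only phenomenologically through the fitted Hill
coefficient); stochastic single-cell kinetics.

## Pipeline and reproducibility

A run configuration (YAML or dict) selects simulate or ingest mode,
per-condition drivers (`hill`, `iffl`, or `kinetics`), processing
options and the analysis plan. The global seed is expanded to
per-condition seeds as `SeedSequence([seed, condition_index])`, so any
stage can be rerun in isolation; reports (`summaries.csv`, `fits.json`,
`classification.json`, `run_log.json`) are plain text and byte-identical
across reruns of the same config. Config schema violations are reported
with field paths before any work starts; per-condition failures are
logged and reported without corrupting completed outputs.

## Problem sizes used in tests and the acceptance script

Populations of 10,000 events per read (2,000–5,000 in fast unit tests);
dose grids of 9–16 points over 0.005–50 µM; 50 seeded replicates per
truth value for noisy-recovery checks; bootstrap n_boot = 200 with
400 events/dose at ~20% event CV (≈1% standard error on the median,
the "1% noise" regime); interval-coverage checks over 100 simulated
replicates. Monte-Carlo oracles run at 10× the tested event count.

## Known limitations

- The fitted numbers of the original experiments are not recomputable —
  the raw cytometry data were never deposited — so quantitative
  agreement is demonstrated against synthetic ground truth, with the
  published values used only to set realistic regimes (fold changes of
  ~2–10, Hill coefficients 1.5–2.1, band-pass peak near 1 µM).
- Percentile bootstrap intervals are first-order; no BCa correction.
- The QSS binding approximation slightly misstates transients when
  binding is slow; use explicit-binding mode if that matters.
- The VYB batch-offset rule follows the published recipe literally
  (|batch min| + 1), which shifts values even when the batch minimum is
  positive; that is the documented behaviour of the original procedure.
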