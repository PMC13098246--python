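# Methods

## Thermodynamic model

The package treats a fermentation pathway as an ordered list of reactions
over named metabolites.  The transformed Gibbs energy of reaction *j* at
molar concentrations *c* is ΔrG′ⱼ = ΔrG′°ⱼ + RT·Σᵢ Sᵢⱼ·ln cᵢ; the driving
force is −ΔrG′ⱼ.  ΔrG′° is strictly an input.  The bundled tables for the
three pathway models (EMP + Pdc/Adh, cellobiose-EMP + PFOR/ALDH/ADHP, and
Entner–Doudoroff) carry curated approximate values at pH 7.0 and 0.25 M
ionic strength, typical of component-contribution estimates, rounded to
0.5 kJ/mol; their provenance is stated in each file header.  Water is
omitted (activity 1) and proton/charge balancing is out of scope.  R·T uses
the table's stated temperature (310.15 K for the mesophiles, 324.15 K for
the thermophile); ΔrG′° is *not* re-transformed across temperatures — doing
so would need reaction enthalpies we do not have.  This is a documented
limitation: the bundled energies are fixtures for exercising the method, not
organism-accurate thermodynamics.

## The MDF program

`solve_mdf` maximizes B subject to ΔrG′°ⱼ + RT·(Sᵀx)ⱼ ≤ −B and
ln(lowerᵢ) ≤ xᵢ ≤ ln(upperᵢ), using `scipy.optimize.linprog` (HiGHS).
Bound conventions:

* measured concentration c > 0 → fixed interval (c, c), even above the
  100 mM free ceiling (the fixing rule wins);
* absent/unmeasured → (1 µM, 100 mM);
* measured zero → pinned at (1 µM, 1 µM).  The lower bound is dictated by
  the ln domain; the upper bound is a genuine design choice — pinning
  preserves the "quantified metabolites are fixed" convention.  A
  `zero_measured="free_ceiling"` switch gives the alternative (1 µM,
  100 mM) reading.

The optimal concentration vector is degenerate.  An arbitrary LP vertex
leaves reactions that involve only free metabolites sitting at the minimum
driving force without being genuine constraints, which would pollute the
reported bottleneck set.  A second LP therefore fixes B at its optimum and
maximizes the sum of per-reaction driving-force slacks, each capped at
1 kJ/mol; reactions whose slack stays ≤ tol (default 1e-6 kJ/mol) are the
reported bottlenecks — the steps that *cannot* be moved off the minimum.
Ties are allowed.  Only the MDF value and the bottleneck set are unique;
consumers must not rely on uniqueness of the concentration vector.

`mdf_timecourse` re-derives bounds from that time point's measurements and
solves independently per time point; no smoothing is applied to
measurements before solving.  Time points with no intracellular data are
flagged skipped rather than interpolated.

## Sensitivity analyses

Global relaxation replaces each measured (c, c) by (c/f, c·f), f ≥ 1;
zero-measured entries keep their 1 µM floor and get floor·f as ceiling
(multiplicative rule applied at the floor).  Single-metabolite relaxation
replaces one measured metabolite's bounds by the free (1 µM, 100 mM) box,
keeping all other bounds as measured.  Reports are ranked by mean MDF gain
over the no-production phase.  Two subtleties worth knowing:

* relaxation is monotone (larger f never lowers the MDF), but the large-f
  limit does **not** converge to the all-free MDF: once (c/f, c·f) contains
  the default box the relaxed program dominates the all-free one, and
  pathway-boundary metabolites keep widening, so the MDF keeps growing;
* single relaxation can in principle lower the MDF if a measurement lies
  outside the default box (the replacement is then not a superset); with
  measurements in the physiological range it never does.

## Phase segmentation

The three phases are operationalized from rate thresholds: growth-coupled
while the smoothed OD rate exceeds α (default 0.10) of its maximum;
no-production once the smoothed ethanol rate drops below β (default 0.05)
of its maximum and never exceeds it again (the phase is terminal);
growth-uncoupled between.  The thresholds are configurable and explicit
phase labels in the input override the rule.

The rate estimator is deliberately robust, because near the production
plateau the relevant rates are of the same order as measurement noise on a
large titer: each series is median-filtered (window 5), projected onto the
nearest non-decreasing sequence (isotonic regression — both OD and ethanol
are monotone up to noise in these batch fermentations), smoothed three
times with the centered window-3 rolling mean, and differentiated centrally
with edge slopes clamped to their interior neighbours.  On the synthetic
generator's default conditions this recovers both injected boundaries
within ±1 sample in ≈99 % of runs.  `smooth` itself (the plotting
trendline) remains a single centered rolling mean with truncated edges.

## Clustering

Trajectory heatmaps z-score each metabolite across its own time points
(sample SD, n−1; constant rows become zero rows and are excluded from
clustering with a warning).  Rows are clustered by unweighted average
linkage (UPGMA) on correlation distance (1 − Pearson r) via
`scipy.cluster.hierarchy`; the test suite checks it against an independent
brute-force UPGMA implementation.  Columns stay chronological.  Pearson
correlation is assumed; the distance function is pluggable if another
variant is wanted.

## Quantification

Intracellular volume is the product single-cell volume × OD₆₀₀ × cells/mL
at OD₆₀₀ = 1 × filtered volume, with bundled per-organism constants
(7×10⁻¹³ mL & 8.9×10⁸; 5×10⁻¹³ mL & 4.4×10⁸; 4.5×10⁻¹² mL & 2.2×10⁸).
Rod-shaped cells are approximated as cylinders (π r² L).  Calibration
curves are ordinary least squares with a free intercept (the functional
form is not otherwise constrained); peak areas below the intercept are
below the quantification limit and clip to 0 mM with a warning.
Extracellular HPLC values are accepted as already-calibrated mM or g/L.

## Synthetic data generator

The generator emulates the *shapes* of high-substrate batch fermentations,
with defaults mirroring an engineered E. coli condition: 666 mM (120 g/L)
initial glucose, a final ethanol titer of 450 mM reached well before
substrate exhaustion (yield 1.45 mol/mol, leaving >350 mM residual
glucose), OD plateauing at 2.0 when growth ends at 20 h, production ceasing
at 45 h over a 60 h horizon sampled every 2.5 h.  Mechanisms:

* OD follows a logistic whose growth rate falls to the segmentation's α
  cutoff exactly at the injected growth boundary; ethanol production is
  proportional to biomass, gated down by a logistic that reaches the β
  cutoff at the injected cessation time, and literally zero afterwards
  (cessation is modeled phenomenologically, not mechanistically);
* baseline intracellular pools come from a staging LP: every reaction's
  driving force ≥ 60 % of the network's all-free MDF while pools stay as
  close to 1 mM as possible inside a 2 µM – 50 mM box.  A per-seed
  log-normal jitter (σ = 0.15) and a smooth temporal wiggle (σ = 0.05)
  individualize runs while keeping true pools strictly inside the 1 µM –
  100 mM default bound box.  (A purely log-uniform baseline was rejected:
  it makes arbitrary reactions thermodynamically infeasible, so no
  controlled bottleneck ground truth would exist.);
* the injected signal: after growth ends, the designated bottleneck
  reaction's driving force decays exponentially toward equilibrium,
  reaching 0.5 kJ/mol at the cessation time by default.  The required
  mass-action-ratio shift is split across the reaction's non-cofactor
  participants (pep down, pyr up for PYK), so each pool moves only a
  few-fold — reproducing the observed pyruvate-accumulation signature
  without unphysiological concentrations;
* measurement noise is multiplicative log-normal with unit mean:
  CV 10 % for intracellular LC-MS values, 1 % for extracellular HPLC
  titers and 2 % for OD, reflecting the much higher precision of HPLC
  endpoint measurements; bpg, acald, CO₂, phosphate and the ferredoxin
  pool are masked as unmeasured.

What passing tests on this generator do show: the pipeline recovers an
injected near-equilibrium reaction from noisy, partially masked
measurements, ranks its participants top in the relaxation scan, and finds
phase boundaries to one sample.  What they do not show: correctness of the
bundled ΔrG′° values for real organisms, robustness to systematic
(non-multiplicative) measurement bias, matrix effects, quenching artifacts
in cofactor pools, or biological phase shapes beyond the
logistic/exponential family simulated here.

`emit_peak_areas` re-expresses a dataset as LC-MS peak areas (slope drawn
log-uniformly over 10¹²–10¹⁴ area/mol, free intercept, 5 % multiplicative
noise) plus a six-point external-standards table, to exercise the
calibration path end to end.

## Numerical choices

LP solver HiGHS throughout; bottleneck tolerance 1e-6 kJ/mol; driving-force
slack cap 1 kJ/mol in the bottleneck stage; concentrations serialized in mM
(6 significant digits) and energies in kJ/mol (4 decimals); ratio
denominators of zero yield missing values, never infinities; an all-zero
adenylate pool yields a missing energy charge.  The grid-search oracle used
in the tests evaluates the minimum driving force on a 201-point-per-
dimension lattice over the free metabolites' ln-boxes with one refinement
pass around the incumbent; free boxes in the random test networks are kept
≤2 ln units wide so the lattice resolves the optimum far below the
0.05 kJ/mol comparison tolerance.  Problem sizes in the validation runs —
25 random LP-vs-grid networks, 20 seeded bottleneck-recovery runs, 40
phase-recovery runs, 50 clustering-oracle matrices — were chosen to give
stable rates at interactive runtimes.

## Known limitations

* ΔrG′° fixtures are curated approximations; swap in your own table (TSV)
  for organism-accurate work.
* No temperature re-transformation of ΔrG′°; no pH/ionic-strength
  adjustment at run time.
* Phase thresholds operationalize what is, in the underlying experimental
  practice, a visual annotation; boundary placement on real data should be
  reviewed.
* The energy-charge weighting (ATP + ½ADP) is the standard adenylate
  convention; it is configurable only by computing your own series.
* MDF localizes thermodynamic infeasibility; it does not identify the
  biological mechanism (enzyme inactivation, redox imbalance, transport
  loss) behind it.
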