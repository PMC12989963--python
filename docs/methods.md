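# Methods

## Model

The analysis treats routine food-safety sampling as a census of
supply-chain flows.  A *flow* is a (source province *i*, monitoring
province *j*) pair; the source may be the reserved `UNKNOWN` stream when
the product is untraceable.  All estimates pool the configured year
window (2015–2022 by default).

**Contamination flows.**  With `NST` samples tested on a flow, `NSC`
failing for any hazard, and `NSC_k` failing for hazard *k* (a sample
counts once per distinct hazard it exceeds), the per-antibiotic
contamination probability is the conditional decomposition
`ProbC = (NSC/NST) × (NSC_k / Σ_h NSC_h)`.  The occurrence denominator
`Σ_h NSC_h` counts hazard occurrences — a two-hazard sample contributes
twice — so the per-hazard probabilities partition the flow's failure
rate exactly (`Σ_k ProbC_k = a`); this identity is enforced by test.
Flows with `NST = 0` are reported missing, not zero: an untested flow
carries no information, and treating it as clean would understate risk.
Two rates are kept per flow: the all-hazard rate `a` (used for the
all-contaminant detection objective) and the any-antibiotic rate
`a_ant` (used for AR-specific quantities); both are fractions in [0, 1]
everywhere, formatted as percent only in reports.

**Concentrations.**  Mean exceedance concentrations `CL(j, k)` are
pooled over all sources per destination, reflecting the assumption that
a destination's measured levels blend all of its suppliers (origin-
specific concentrations are not observable in this kind of data).  `CL`
is carried in µg/kg throughout; with daily intake `DI` in kg/person/day
and body weight `BW` in kg this makes `EDI = CL·DI/BW` come out in
µg/kg-bw/day, dimensionally consistent with the ADI.

**Risk chain.**  `HQ = EDI/ADI`, `CHQ = ProbC × HQ`,
`HI_j = Σ_{i,k} CHQ`.  Antibiotics without an ADI are excluded with a
warning rather than given surrogate values.  The chain is exactly
linear in the concentrations — the backbone of the ±20 % concentration
sensitivity scenario — and the per-source partial sums
`HI_{i,j} = Σ_k CHQ` are retained because the saved-risk evaluation
needs them.  HI is per-capita per province; no population weighting.

**Food loss.**  `TV = PV − EV + IV` per province-year;
`CTV_all = TV × a_j`, `CTV_ant = TV × a_{j,ant}` with destination-pooled
window rates applied to each year's volume (per-year rates are available
by argument).  Because one sample can exceed several antibiotics, the
per-compound losses `CTV_k` may sum to more than the deduplicated
any-antibiotic loss; the headline uses the deduplicated rate and the
decomposition is reported separately.

**Monitoring schemes.**  A scheme assigns integer batches `x_{i,j}`.
Detection of one source is `d = 1 − (1 − s·a)^x`, the complement of `x`
consecutive clean draws, with assay sensitivity `s` (default 1.0, the
perfect-detection assumption; 0.98 is the HPLC-GC scenario).  The
scheme's effectiveness is the joint probability `h_j = Π_i d_i` over
sources with `a > 0`; zero-prevalence sources are excluded from the
product because there is nothing there to detect (otherwise a single
clean flow would pin `h` at zero regardless of effort).  Saved health
risk is `SHI_j = Σ_i d_{i,ant} · HI_{i,j}`, using antibiotic-specific
detection: HI is an antibiotic-only quantity, so detection of
non-antibiotic hazards cannot remove it.

**Saved food loss** is reported in two readings, both always present:

* `STV_as_printed = (Σ_y CTV_ant / Y) × (1 − a_ant·g)` — the literal
  published form.  It *decreases* as detection improves, which
  contradicts the surrounding narrative that better monitoring saves
  more food; the discrepancy is documented here rather than silently
  resolved.
* `STV_intercepted = (Σ_y CTV_ant / Y) × g` — the detection-removes-loss
  reading: the fraction `g` of the mean annual AR loss that the scheme
  intercepts.  Comparisons and the acceptance summary use this column
  for "saved loss" because its deltas have the sign the comparison
  narrative requires.

**Optimization.**  Per province (the problems are separable; national
figures are sums), maximize `h_j` subject to (i) the batch budget, (ii)
a floor on post-removal trade volume `TV_latest × (1 − a_j·h) ≥ TV_mean`
— in the default *decision* mode the floor uses the candidate scheme's
own `h`, so it caps how much volume the scheme may remove; a *baseline*
mode checks it at fixed baseline detection instead — (iii) residual
hazard index `HI_j − SHI_j ≤ 1`, and (iv) integrality.  The log
objective `Σ_i log(1 − q_i^{x_i})` has decreasing integer increments, so
greedy marginal allocation is exact for the budget-only problem; gain
ties prefer the higher source index, which yields the lexicographically
smallest optimal allocation (the documented tie-break).  Side
constraints are handled by screening: if the budget-only optimum already
satisfies them it is globally optimal; otherwise an exact levelwise
dynamic program over partial allocations solves small instances
(state-count guard 5·10⁵; Pareto pruning on partial (h, SHI) is applied
only when no cap on the objective is active, because a cap breaks the
dominance argument), and a greedy construct-repair-swap heuristic
handles larger ones, flagged non-optimal.  An exhaustive enumeration
oracle (≤ 4 sources, budget ≤ 15) verifies both exact paths on randomly
generated constrained instances.

Degenerate cases: a budget below the number of positive-prevalence
sources cannot achieve `h > 0`, and the canonical representative (the
empty scheme) is returned; a residual-risk floor unsatisfiable even at
full budget returns the maximum-saved-risk allocation flagged
infeasible; a trade-volume floor already breached at `x = 0` is flagged
and dropped (the floor cannot be restored by sampling less).
Constraint tolerances: 10⁻⁹ absolute on probabilities, 10⁻⁶ tons on
volumes.

## Synthetic data

The generator is the forward model the estimators invert.  Defaults are
fixed once as the study conditions:

* 31 provinces × 2015–2022, 1,200 samples per province-year (~300k
  records) in the study-scale preset; any sizes via
  `make_ground_truth` / `generate_dataset`.
* Flow shares per monitor: 0.50 internal, 0.26 external, 0.24 unknown.
  External trade goes to 2–8 neighbouring provinces (varying across
  monitors so source-diversity regressions have support) with
  geometrically decaying shares (ratio 0.7).
* True any-antibiotic contamination rates per stream: mean 0.6 %
  (internal), 1.9 % (external), 1.6 % (unknown) with small per-flow
  jitter — the published stream magnitudes.  Internally these are
  converted to all-hazard failure probabilities through the hazard mix's
  antibiotic occupancy.
* Failed samples carry 1 hazard with probability 0.9 and 2 with
  probability 0.1 (second draw with replacement, duplicates collapsed),
  so the multi-hazard occurrence denominator is exercised.
* Exceedance concentrations are log-normal truncated below at the MRL
  (strictly above 0 for zero-tolerance compounds), log-sd 0.35; only
  means are identified by the estimators, the family is a modelling
  choice.
* The 15-compound reference panel uses realistic MRLs (0–500 µg/kg) and
  ADIs; the three banned compounds carry sub-ng virtually-safe-dose
  ADIs so that cumulative risk is dominated by zero-tolerance compounds
  and provinces can exceed HI = 1 at realistic intakes.
* Trade follows smooth 3 %/year growth paths with 1 % noise (so the
  latest year's volume sits above the historical mean and the
  trade-volume floor stays satisfiable); exports and imports are fixed
  fractions (15 % / 8 %) of production.
* Unknown-source samples draw a latent true origin and erase it; the
  latents are kept for diagnostics (`SyntheticDataset.latent_origins`),
  matching the reading of "unknown" as untraceable rather than
  originless.
* All randomness flows from one seed through stage-keyed substreams, so
  datasets are bit-reproducible.

The preset's daily intakes are set from the closed-form expected hazard
index so that exactly six provinces sit well above HI = 1 (expected
values 2.0–4.5) and the rest well below (≤ 0.5).  The wide separation is
deliberate: measured HI carries ~±30 % sampling noise (Poisson counts of
the dominant banned-compound occurrences), and the margins keep the
exceedance count and the top-6 ranking stable across seeds and across
the sensitivity grid.  The implied intakes span ~0.01–0.3 kg/person/day.

What the generator does *not* emulate: real spatial structure (gravity
trade beyond ring-neighbour shares), temporal trends in contamination,
product-category heterogeneity, origin-dependent concentration
distributions, and reporting artefacts of scraped disclosure data.
Passing tests therefore demonstrate that the estimators and the
optimizer are correct for the assumed sampling process at realistic
magnitudes — not that real surveillance data satisfies those
assumptions.

## Sensitivity analysis

One-at-a-time deterministic scenarios: contamination probabilities
×0.9/×1.1, concentrations ×0.8/×1.2, assay sensitivity 0.98, plus the
two combined corners (both-up, both-down).  Perturbations are
multiplicative (consistent across both parameter families) and
probabilities are clipped back into [0, 1] with clip events logged.
The identity scenario skips the arithmetic entirely, so it reproduces
baseline outputs bit-exactly.  Stability is summarized as top-k set
overlap (Jaccard and exact-set) against the first scenario and the
sign-stability of the per-province optimizer advantage.

## Numerical choices

* Detection probabilities use `expm1`/`log1p` forms to stay accurate for
  small `s·a` and large `x`.
* Greedy heaps order ties by higher source index (lexicographic
  tie-break); the enumeration oracle breaks objective ties to the
  lexicographically smallest allocation, and the two conventions agree.
* The diversity regression (stream rate against the count of distinct
  traceable source provinces, pooled per monitor) is OLS via
  statsmodels; a flat response returns slope 0 with R² = 0, and constant
  diversity raises rather than returning an arbitrary fit.
* Daily intake is averaged over reported years per province before
  entering EDI.

## Known limitations

* The exact DP enumerates partial allocations and is intended for
  verification-scale instances; study-scale constrained instances fall
  back to the repair heuristic (flagged) whenever screening fails.
* `STV_as_printed` retains the published formula's counter-intuitive
  direction; downstream consumers must choose the reading explicitly.
* Concentration pooling across sources means source-resolved risk
  attribution rests entirely on `ProbC`, not on concentration
  differences between origins.
* The optimizer treats budgets as batch counts with homogeneous cost;
  no monetary cost heterogeneity, multi-year dynamics, or strategic
  response by suppliers.
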