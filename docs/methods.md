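# Methods

## Problem and data model

A mortality event is summarised by the scratch densities of its individuals.
One specimen yields one density: scratches are counted in up to two standard
0.16 mm² areas per tooth and the counts averaged; a specimen with a single
countable area contributes that count alone (the most conservative reading
of two-area averaging). A sample of n individuals is reduced to the pair

* SD — sample standard deviation of the densities (denominator n − 1),
* CV = SD / mean — the dimensionless coefficient of variation,

which are the x and y coordinates of everything that follows. The n − 1
convention is a package choice (the conventional unbiased-variance
estimator); `variability_point(..., ddof=0)` switches to the
maximum-likelihood denominator, which is also what the scikit-learn
cross-check in the test suite uses.

Two mechanisms generate dispersion. Individuals that die on the same date
differ (age, sex, health): within-date heterogeneity. And the mean density
follows the seasons — abrasive graze raises it in spring/summer, browse
lowers it in fall/winter — so deaths spread over more of the year add
between-date variance. Short events (scenario A: one month to a season)
mostly show the first source; long events (B: four months to a year) add the
seasonal sweep; two short events in opposite seasons (C) put all the
seasonal contrast into a bimodal mixture, inflating SD and CV beyond the
continuous case.

## Seasonal simulator

The synthetic generator is the package's stand-in for dated reference
collections. Expected density on day-of-year d is a single-harmonic cosine

```
μ(d) = baseline + amplitude · cos(2π (d − peak_day) / 365)
```

(shifted 182 days for Southern-Hemisphere populations; leap days ignored —
irrelevant at month/season resolution). Individual densities are normal
around μ(d) with standard deviation `individual_sd`, truncated at zero.
The cosine is the minimal model with the attested ordinal structure (one
seasonal peak in spring or summer, trough in fall/winter); real seasonal
profiles are neither perfectly sinusoidal nor identical across years, and
the simulator deliberately omits year effects, weather shocks, age/sex
structure and diet switching, so passing tests demonstrate correct behaviour
under idealised seasonality, not under every real collection.

Defaults (in `mortwear.config`, units: scratches / 0.16 mm²):

| parameter | default | why |
|---|---|---|
| baseline | 14.0 | published per-sample means span ≈ 9–18 |
| amplitude | 5.5 | year-long reference samples reach SD ≈ 4.5–4.7 with CV ≈ 0.26–0.36; a uniform year of the cosine contributes SD ≈ amplitude/√2 |
| peak_day | 135 (mid-May) | between the spring peak seen in caribou and the summer peak in mule deer |
| individual_sd | 1.3 | the two day-resolution reference samples show within-event SD ≈ 0.8–1.1; season-scale ones reach ≈ 2.2 |

The default training recipe additionally cycles `individual_sd` through
(0.9, 1.3, 1.7, 2.1) across sub-samples so each class reflects
between-population differences in individual spread rather than a single
idealised herd. With these values, simulated scenario points span the
published reference envelope (SD ≈ 0.8–7, CV ≈ 0.08–0.36); the balanced
scenario-C points exceed its CV edge (up to ≈ 0.45) by construction — two
fully opposite short events are more extreme than any continuous published
sample, and the envelope's upper-right corner is exactly where region C
must sit.

## Training-set rules

A sub-sample enters training only when its dates match one scenario without
ambiguity: n ≥ 15 (below that, the mean sample SD correlates negatively with
n — `sd_vs_n_bias` demonstrates the effect — so smaller sets are discarded);
a window ≤ 92 days for A, 120–365 days for B; and, for A/B, deaths "evenly
distributed" — operationalised as (i) no inter-death gap longer than 1/3 of
the window and (ii) no 1/6-window bin holding more than half the deaths
(both thresholds config-exposed; a `relax` flag disables the evenness rules,
never the size rule). Scenario C sub-samples are two groups from
non-consecutive seasons — "non-consecutive" meaning separated by an
intervening meteorological season (month triplets DJF/MAM/JJA/SON,
hemisphere-flipped): spring↔autumn or winter↔summer. Because two seasons
are rarely equally represented, one group's densities are replicated
cyclically (no new values introduced) over a nine-value warm-season
proportion grid 0.1–0.9, covering the spectrum of two-event imbalances.

The default recipe simulates 8 A-windows (a mid-season month and a full
season, per season), 8 B-windows (lengths 150–365 days at staggered
phases), and 9 C-points (30-day events at the seasonal peak and trough,
days 121–150 and 303–332, over the proportion grid), 30 individuals per
A/B sub-sample.

## Classifier

Each class k gets `G_k(x,y) = P_k · N(x; μ_xk, σ_xk) · N(y; μ_yk, σ_yk)`
with parameters set to the class's sample means and SDs on each axis and
equal priors P_k = 1/3 (no prior information on real case frequencies;
user-supplied priors are accepted, enabling informed re-weighting without
any built-in recursion). The plane is partitioned by argmax_k G_k; ties
(a measure-zero event) break deterministically in the order A < B < C.

Numerics:

* **Grid.** All boundaries, maps and integrals are evaluated on a 500×500
  cell-centre grid, default SD ∈ [−1.5, 10], CV ∈ [−0.10, 0.60]. The bounds
  cover every published coordinate with a margin and extend a few class-SDs
  past the fitted modes so that grid quadrature captures essentially all
  mixture mass (the Gaussian model assigns a small, harmless mass to
  negative SD/CV; it is integrated, not clipped). Bounds and resolution are
  user-configurable.
* **Boundaries.** Zero contours of log G_i − log G_j, extracted with
  contourpy (matplotlib's contour engine) rather than by symbolically
  solving the quadratic locus; vertices satisfy |log G_i − log G_j| < 0.02
  at the default resolution. Only (A, B) and (B, C) matter; (A, C) is
  computed on request with a warning.
* **Uncertainty map.** The published closed-form "variance of the
  classifier" is not recoverable from the source figures; the implemented
  heat map is 1 − max_k posterior, which has the described behaviour —
  coloured bands along the boundaries giving the probability that a case in
  a region does not belong to it (0.5 on a two-class boundary with the third
  class negligible). A top-two-margin variant is available
  (`error_map(kind="margin")`).
* **Isolines.** For each mass m ∈ {0.68, 0.95, 0.995} the level c with
  ∫_{G≥c} G = m is found by bisection on c against grid quadrature, then
  contoured. 0.995 (not 0.997) is the default third mass, user-overridable.
  A grid too small to contain mass m raises an error instructing
  enlargement. An independent Monte-Carlo integration (10⁶ mixture draws)
  confirms the enclosed masses to within ±0.1 percentage point at defaults.
* **Expected total error.** Σ_k ∫_{outside region k} G_k by grid
  quadrature — algebraically 1 − ∫ max_k G_k, an identity the tests check —
  with the A–C cross term reported separately so its negligibility is
  verifiable (≈ 10⁻³ at defaults, against a total of ≈ 0.15–0.23 depending
  on the training seed, dominated by B/C overlap).

## Calibration and validation

The simulator and recipe defaults above were fixed once, so that the
generated scenario classes occupy the same parts of the plane as the
published training map. Validation is held-out: the fitted map, trained
purely on synthetic sub-samples, classifies the six published extant samples
that played no part in training by their printed coordinates — the five
short/seasonal samples (day-scale elk and pronghorn die-offs, seasonal sika
deer, guanaco, and the small multi-year elk set) land in region A and the
year-long pronghorn sample in region B, reproducing the published held-out
split; the eleven archaeological samples reproduce the published regional
reading (seasonal A for Portel-Ouest herbivores except the horse,
Salzgitter Lebenstedt, Arago L; long-term B for the Portel-Ouest horse and
Taubach bison; separated events C for Abric Romaní K and Arago J, with
Arago G a B/C boundary case). These outcomes are stable across training
seeds (50/50 in a seed sweep).

## Degenerate inputs and edge cases

SD needs n ≥ 2 and CV a positive mean; both raise informative errors.
A class with fewer than two training points, or zero within-class variance
on either axis, refuses to fit (with a remediation hint). Records may carry
month-only death dates (placed mid-month for date arithmetic) and
single-area counts; missing values are parsed as missing, never zero.
Record CSVs round-trip bit-identically (floats serialised with `repr`).

## Known limitations

* Region geometry depends on the synthetic training conditions; the exact
  fitted (μ, σ) of the original map are unpublished, so agreement is
  assessed at the level of region membership, not parameter values.
* The recomputation of published per-sample statistics from the deposited
  per-individual raw data runs only when a user places those files under
  `data/dryad/` (they are an external download); the equivalent machinery is
  exercised on generated individual-level records in the test suite.
* Scenario C covers exactly two groups; more than two episodes, or episodes
  in consecutive seasons, fall outside the three-scenario vocabulary and
  will land near boundaries by design.
* No recursive prior updating, full-covariance or kernel classifiers, or
  automated sub-sample search.
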