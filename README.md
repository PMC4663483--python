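# mortwear

**How long did a mortality event last?** Assemblages of ungulate teeth — from
modern mass die-offs or Palaeolithic hunting sites — accumulate over very
different time spans: a single catastrophic day, one season of winter
mortality, attritional death over years, or repeated short occupations in
different seasons. Because dental microwear turns over within days to weeks
of death (the "Last Supper Effect"), the *variability* of scratch density
across the individuals of an assemblage encodes the duration of the
accumulation: scratch densities track diet, diet tracks season, so deaths
spread over more seasons disperse more.

`mortwear` implements a classifier of mortality-event duration for
zooarchaeologists and palaeoecologists working from non-destructive
microwear counts. Each specimen contributes one scratch density (mean of two
counts per standard 0.16 mm² enamel area); each sample of n ≥ 15 individuals
becomes a point (SD, CV) — standard deviation and coefficient of variation
of those densities. Neither measure separates the durations alone, but their
combination does, into three scenarios:

* **A** — deaths within one month up to one season (short event),
* **B** — deaths over four months up to a year (long-continued event),
* **C** — two separated short events in non-consecutive seasons.

## The model

Each scenario k ∈ {A, B, C} gets a weighted axis-aligned bivariate Gaussian
over the plane (x = SD, y = CV):

```
G_k(x, y) = P_k · N(x; μ_xk, σ_xk) · N(y; μ_yk, σ_yk),   P_A = P_B = P_C = 1/3
```

a Gaussian naive-Bayes model: SD and CV are treated as independent within a
class, so only per-axis means and standard deviations are estimated — tiny
training sets suffice. The plane splits into three regions by
argmax_k G_k(x, y); boundaries are the loci G_i = G_j, the heat map
1 − max_k posterior shows how unreliable an assignment near a boundary is,
and isolines of the total mixture G = ΣG_k enclosing 68 / 95 / 99.5 % of the
probability mass delimit where new cases can be meaningfully classified.
Training points come from scenario-labelled sub-samples of dated death
records — here generated by a calibrated seasonal simulator (sinusoidal
seasonal mean, high spring/summer and low fall/winter, plus within-date
individual heterogeneity); sub-samples below fifteen individuals are
rejected because the sample SD is biased low at small n.

## Worked example

```python
import mortwear as mw

points = mw.synthetic_training_points(seed=1)       # 25 labelled (SD, CV) points
res = mw.DurationClassifier.from_points(points).fit()
print(res.summary())
```

```
Mortality-duration naive-Bayes classifier (SD-CV plane)
============================================================
 class   prior    mu_SD    sd_SD    mu_CV    sd_CV     n
     A   0.333    2.030    0.631    0.156    0.070     8
     B   0.333    4.164    0.850    0.304    0.073     8
     C   0.333    4.774    0.823    0.362    0.085     9
------------------------------------------------------------
expected total error: 0.2267   (A-C overlap term: 1.22e-03)
grid: 500x500 over SD [-1.5, 10.0], CV [-0.1, 0.6]
```

Class A (short events) sits at low SD and low CV, B (long events) disperses
both measures, C (two opposite-season events) pushes both further still. The
expected total error is the mixture mass each class leaves in the others'
regions — the B/C overlap dominates it, while the A–C term is negligible.

Classifying the Taubach bison sample by its published coordinates
(SD 4.134, CV 0.242):

```python
r = res.classify(4.134, 0.242)
print(r.region, r.posterior, r.error_prob, r.inside_isoline)
# B {'A': 0.003, 'B': 0.740, 'C': 0.257} 0.260 0.68
```

Region **B**: a long-term accumulation (with a 0.26 probability of not
belonging to B — the point lies towards the B/C boundary), inside the 68 %
isoline of the training mixture. The same call over all eleven published
archaeological samples reproduces the interpretations derived from
independent archaeological evidence: seasonal hunting episodes (region A)
for the Portel-Ouest reindeer/red deer/bovids, Salzgitter Lebenstedt and
Arago level L; long accumulations (B) for the Portel-Ouest horses and
Taubach; separated seasonal occupations (C) for Abric Romaní level K and
Arago level J.

From the shell, the same pipeline is:

```
mortwear run --seed 1 --out-dir demo      # points.csv, model.json, results.csv, map.png
mortwear tables --which fossil            # the built-in published coordinates
mortwear simulate --scenario C --n 30 --seed 7 --out c.csv
mortwear stats --records c.csv
```

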