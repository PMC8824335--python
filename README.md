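# locpattern

Analysis toolkit for free-field sound-source localization data from listeners
with bilateral cochlear implants (BiCIs). In the underlying task a noise burst
is played from one of 19 loudspeakers spanning ±90° azimuth in 10° steps and
the listener reports the perceived direction on a touchscreen (responses
restricted to ±90°, typically 15 repetitions per speaker). `locpattern`
implements four complementary measures of localization performance and the
statistics that connect them to patient factors such as age at onset of
deafness:

1. **RMS error** — overall and per-target-angle root-mean-square deviation of
   response from target, with the natural-log per-angle values feeding a
   random-intercept mixed model
   `log RMS ~ OD + STA + OD×STA + (1 | listener)`
   (OD = onset-of-deafness group, early ≤ 5 y vs late; STA = squared target
   angle), with Satterthwaite denominator degrees of freedom.
2. **Localization sensitivity index (LSI)** — for each of the C(19,2) = 171
   target-angle pairs, a Kruskal–Wallis rank test compares the two response
   samples; its p-value is mapped to a positive z-score
   (z = Φ⁻¹(1−p), floored at 0) and the LSI is the mean z. High values mean
   well-separated response distributions, akin to an average d′.
3. **Four-parameter logistic (4PL) fits** — each listener's target→response
   function is fit with
   `y = β + (α−β)·S((μ−x)/σ)`, `S(t) = 1/(1+e^(−t))`,
   by bounded trust-region least squares from the fixed start
   (α, β, μ, σ) = (90, −90, 0, −50); the response range α−β and slope σ are
   the derived features.
4. **Bootstrap + k-medoids pattern classification** — the package's
   centerpiece. A listener's 38-value summary (19 per-angle response means ⧺
   19 per-angle SDs) is clustered, together with 1000 simulated subjects
   (50 bootstrap draws from each of 20 pattern categories = 5 mean shapes ×
   4 SD shapes), by partitioning around medoids (PAM, classical BUILD+SWAP,
   k = 20, Euclidean distance). The listener inherits the modal true category
   of its cluster; 50 repetitions with fresh reference cohorts yield a
   reliability histogram whose mode is the final category.

Downstream inference includes stepwise-AIC model selection with a |r| > .75
collinearity screen, uncorrected 2×2 chi-square tests of category membership
by onset group, Monte-Carlo power for that test, and Pearson correlations.
A synthetic-data module generates all categories, cohorts with known
regression structure, and the 48-listener demographic table used as a
fixture.

## Worked example

```python
import locpattern as lp

# a listener who hears everything near the center of the head
subject = lp.simulate_subject(lp.make_category("Flat", "Ideal"), reps=15, rng=123)
trials = subject.dataset.trials

rms = lp.rms_error(trials, lp.ANGLE_GRID)
sens = lp.lsi(trials, lp.ANGLE_GRID)
fit = lp.fit_logistic(trials)
print(f"overall RMS {rms.overall_rms:.2f} deg, LSI {sens.lsi:.2f}, "
      f"4PL range {fit.range:.1f} deg")

summary = lp.summarize(subject.dataset, "SIM")
result = lp.classify(summary, n_runs=10, n_per_category=10, rng=7)
print(result.final_category, dict(result.reliability))
```

Output:

```
overall RMS 55.26 deg, LSI 0.64, 4PL range 1.6 deg
Flat,Ideal {'Flat,Ideal': 10}
```

Reading: a center-clamped responder earns an overall RMS near the
closed-form √3000 ≈ 54.8° (the RMS of a constant-0 responder over this
grid), an LSI near zero (response distributions barely separate across
targets), a collapsed 4PL range, and unanimous assignment to the Flat-means /
Ideal-SDs pattern category — four views of the same inability to localize,
of which only the classifier names the *pattern*.

The same pipeline runs end-to-end from the shell:

```bash
locpattern run --synthetic --subjects 12 --seed 1 --fast --outdir out/
```

writing `metrics.csv`, `fits.csv`, `categories.csv`, `reliability.csv` and a
schema-validated `report.json` (regressions, chi-square tests, correlation,
power), reproducibly for a given seed. `--fast` uses 10 classification runs
with 10 reference subjects per category; the full-scale protocol is 50 × 50.

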