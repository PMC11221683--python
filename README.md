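# wingsync

Quantitative analysis of *Drosophila* indirect-flight-muscle (IFM) function
from two complementary readouts:

1. **Wing-beat synchrony.** A tethered fly is recorded with two infrared
   proximity sensors, one per wing, sampled into a two-column CSV. Flies
   with damaged myofibrils generate uneven contractile force, so their
   left and right wings lose phase coherence. The pipeline detects flight
   bouts, draws *K* = 50 random 5-ms windows inside them, computes the
   Pearson correlation *r* between the two channels in each window,
   classifies a window as a **synchronized event** when *r* > 0.5, and
   pools events across flies into a proportion with an exact binomial 95%
   confidence interval. It also recovers the wing-beat fundamental
   (~200 Hz in healthy flies) from the sensor spectrum, undoing the
   frequency doubling that a unimodal sensor response imposes.
2. **Myofibril phenotype statistics.** Confocal images of IFM are scored
   for ruptured, frayed and enlarged-Z-disc myofibrils out of the 10–15
   myofibrils per image. The package computes affected-myofibril ratios
   (class count / total count, pooled over images), Clopper–Pearson exact
   binomial CIs, the continuity-corrected two-sample test for equality of
   proportions, circular-ROI mean-gray intensity measurements (radius
   4 px, the ImageJ "enlarge" convention), and Welch two-sample *t*-tests
   with Bonferroni correction.

Because the original recordings and micrographs are not machine-readable
inputs, the package ships a first-class synthetic-data module
(`wingsync.simulate`) that generates dual-wing recordings through an
explicit sensor model (peak response at 0.635 mm, 3 mm range, ADC
quantisation), phenotype count tables, and intensity tables with known
ground truth — the substrate for every test in the suite.

## The statistics in brief

For a window of paired samples $(x_i, y_i)$ the synchrony statistic is the
product-moment correlation

$$r = \frac{\sum_i (x_i-\bar x)(y_i-\bar y)}
           {\sqrt{\sum_i (x_i-\bar x)^2 \sum_i (y_i-\bar y)^2}},$$

an event being synchronized iff $r > 0.5$ (strict). The pooled proportion
of synchronized events over $n$ non-degenerate windows gets the
Clopper–Pearson interval, the $(\alpha/2, 1-\alpha/2)$ inversion of the
binomial tails. Two pooled proportions are compared with the Yates
chi-square on the 2×2 table, each cell contributing
$(\max(|O-E|-\tfrac12,0))^2/E$ with df = 1. Intensity groups are compared
with Welch's $t$ with Welch–Satterthwaite degrees of freedom, and
$p_{\mathrm{adj}} = \min(1, m\,p)$ over the $m$ requested pairs.

## Worked example

```python
from wingsync import (SimConfig, simulate_recording, analyze_recording,
                      AnalysisParams, summarize_events)

pool = []
for fly in range(10):
    cfg = SimConfig(duration_s=2.0, coupling_mode="drift", noise_sd=2.0,
                    phase_jitter_sd=0.02, freq_mismatch_hz=15.0,
                    seed=1000 + fly)
    pool += analyze_recording(simulate_recording(cfg),
                              AnalysisParams(seed=2000 + fly))
s = summarize_events(pool)
print(f"{s.n_synchronized}/{s.n_events} synchronized = "
      f"{s.proportion_synchronized:.3f} (95% CI {s.ci_low:.3f}-{s.ci_high:.3f})")
```

prints

```
146/500 synchronized = 0.292 (95% CI 0.252-0.334)
```

ten flies whose wings drift independently produce 500 analysis windows of
which 146 have *r* > 0.5 — well below the ≈1.0 of phase-locked controls,
because a drifting left–right phase only occasionally passes through
alignment. The `examples/` directory holds one short script per
capability (synchrony classification, frequency recovery, phenotype
ratios, intensity comparisons); each prints the numbers it computes and a
line on what they mean.

A thin CLI mirrors the library for batch work:

```bash
wingsync simulate-recording --mode locked --duration 2 --noise-sd 2 --seed 5 -o fly.csv
wingsync analyze-sync fly.csv --seed 6 -o events.csv
wingsync prop-test --k1 5 --n1 50 --k2 20 --n2 50
```

Every stochastic subcommand takes `--seed` and writes a JSON run manifest
next to its outputs.

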