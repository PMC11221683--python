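# Methods

## The generative model

### Sensor geometry

Each wing is tracked by an infrared reflectance sensor whose response is
unimodal in wing–sensor distance: maximal at `sensor_peak_mm`
(0.635 mm, the QRD1114 characteristic) and zero beyond `sensor_max_mm`
(3 mm). The functional form of the real part's response curve is not
documented, so the simulator uses one smooth unimodal shape: a Gaussian
in distance centred at the peak with
σ = (max − peak)/3, baseline-shifted to reach exactly zero at the cutoff
and clipped beyond it, then scaled to the ADC full range
(2¹⁰ − 1 = 1023 counts by default). Gaussian sensor noise
(`noise_sd`, ADC counts) is added before quantisation; quantisation is
round-half-up with clipping to the ADC range.

The wing trajectory is sinusoidal in phase:
`d_w(t) = rest_distance + amplitude · sin(φ_w(t))`. When the stroke
straddles the peak-response distance the sensor output crosses its
maximum twice per beat, so the signal's dominant spectral component sits
at **twice** the beat frequency; with `rest_distance = sensor_peak` the
response is an even function of the stroke displacement and the odd
harmonics (including the fundamental) vanish identically. This
frequency-doubling is a property of the hardware geometry, not an
artefact of the simulator, and the frequency estimator must undo it.

### Phase coupling modes

* **locked** — both wings share the base phase 2π·f·t; each carries an
  independent stationary Ornstein–Uhlenbeck phase perturbation with
  stationary sd `phase_jitter_sd` (radians) and a 10-ms correlation time
  (about two beat periods), the right wing shifted by `phase_offset_rad`.
  An OU perturbation keeps the left–right relative phase *bounded*, which
  is what phase locking means physically: a freely diffusing per-sample
  jitter would decohere the wings completely over a multi-second
  recording at any non-zero sd, making "locked with small jitter"
  indistinguishable from drift. The 10-ms correlation time makes the
  jitter smooth on the sample scale (so the spectrum keeps a narrowband
  line and the bout detector still sees flight) while decorrelating
  between distant analysis windows.
* **drift** — the phases evolve independently: uniform random initial
  phases, independent Wiener phase diffusion with per-sample increment sd
  `phase_jitter_sd`, and a constant frequency mismatch
  `freq_mismatch_hz` on the right wing. With a mismatch Δf the relative
  phase sweeps uniformly, and because the doubled signal correlates as
  cos(2Δφ), roughly one third of windows exceed r = 0.5 — which is why
  drifting recordings settle near 0.3, below the 0.5 acceptance line.
* **intermittent** — locked oscillation alternating with rest segments.
  Bout and rest durations are gamma(shape = 4) with means `bout_on_s` /
  `bout_off_s`, floored at 100 ms so every generated bout is resolvable
  by the default detector; the ground-truth intervals are stored in
  `Recording.meta["true_bouts"]`.
* **no_flight** — rest level throughout except sparse isolated
  single-beat cycles (Poisson, 0.5 events/s), mimicking flightless flies
  that occasionally produce one double-wing movement. Rest is the
  constant sensor response at `rest_distance` plus noise.

Left-wing jitter, right-wing jitter, bout placement and sensor noise draw
from four independent substreams of one seeded generator
(`SeedSequence.spawn`), so toggling noise does not move bouts and the
whole recording is bit-reproducible given `seed`.

Defaults: beat 200 Hz (tethered *Drosophila*), fs 10 kHz (unknown for the
original microcontroller; chosen so a 5-ms window holds 50 samples, well
above the ≥3 needed for a Pearson r), amplitude 0.4 mm about a rest
distance equal to the sensor peak, 10-bit ADC.

### Count and intensity fixtures

Phenotype counts: per image, the myofibril total is uniform on 10–15 (the
typical per-image count) and each myofibril independently takes at most
one phenotype class (multinomial over ruptured / frayed / enlarged /
unaffected), so class counts are binomial given the total and can never
sum past it; probability vectors summing over 1 are rejected. Intensities
are log-normal per disc class — `exp(N(log mean, sd))` with sd on the log
scale — so values are positive, sd = 0 returns the mean exactly, and
moderate sds give the mild right skew of fluorescence data.

## The synchrony pipeline

**Bout detection.** A sample is active when the centred 25-ms rolling
standard deviation of either channel exceeds `k_sigma` (= 4) times the
baseline noise sd, estimated from the lowest-variance decile of samples
and floored at 0.5 counts (a noiseless rest trace would otherwise give a
zero threshold). Active runs shorter than 50 ms are discarded. A
recording with no internal variance contrast (continuous flight, or rest
throughout) has no rest decile to calibrate against, so it is classified
wholesale: the quietest 100-ms slice is checked for a narrowband spectrum
(Welch periodogram peak > 50× the median bin) — oscillation everywhere
means one full-length bout, broadband noise means no bouts. The quietest
slice is used so that sparse transients (the isolated cycles of
flightless recordings) cannot masquerade as continuous flight.

**Windows and classification.** Up to 50 window starts are drawn
uniformly *without replacement* from the positions whose full 5-ms window
fits inside a bout; restricting to bouts keeps rest windows from diluting
the event pool, since the assay analysed continuously flying animals.
Fewer admissible positions than requested returns them all with a
shortfall flag; none (a flightless recording) returns an empty draw
rather than an error. r is computed on raw ADC values without detrending
or filtering. Zero-variance windows get a third label, `degenerate`, and
are excluded from the proportion denominator — how such windows were
handled originally is unstated, and silently counting them either way
would bias the proportion. Classification is strict: r exactly at the
threshold is unsynchronized. Pooling across flies sums events (the event
count n is the reported denominator) rather than averaging per-fly
proportions.

**Frequency estimation.** Per channel, the Welch periodogram
(nperseg ≤ 8192, ≈1.2 Hz resolution at 10 kHz) of the longest bout gives
the peak f*. If at least 10% of the peak power sits at f*/2, the peak is
read as the second harmonic of a visible fundamental and f*/2 is
reported. Otherwise f* is halved until it falls within the plausible
wing-beat band (≤ 300 Hz; tethered flies beat at roughly 150–250 Hz).
The band fold is needed because a perfectly symmetric stroke leaves *no*
spectral trace of the fundamental: a doubled 200 Hz beat (lines at 400,
800, 1200 Hz) is spectrally identical to a genuine 400 Hz beat with even
harmonic distortion, so no data-driven rule can separate them and the
estimator resolves the ambiguity with the physiological prior. Both
estimates are averaged; flat signals, missing bouts, and bouts shorter
than 20 beat periods are errors.

## The statistical primitives

* **Clopper–Pearson interval**: the exact inversion of the binomial
  tails, evaluated with the beta-quantile closed form
  (`Beta(α/2; k, n−k+1)` lower, `Beta(1−α/2; k+1, n−k)` upper; 0 and 1 at
  the k = 0 / k = n boundaries). The tests cross-check it against an
  independent bisection of the binomial CDF to 1e-9.
* **Two-proportion test**: Yates-corrected chi-square on the pooled 2×2
  table, each cell contributing `(max(|O−E|−0.5, 0))²/E`, df = 1,
  two-sided p from the upper chi-square tail. The cap matters for tiny
  deviations (|O−E| < 0.5 gives a zero statistic, not a negative
  correction). A pooled proportion of exactly 0 or 1 yields statistic 0,
  p = 1, with a warning. Per-genotype ratios are pooled counts (sum of
  class counts over sum of totals), not per-image means.
* **Welch t-test**: unequal-variance t with Welch–Satterthwaite df
  (via scipy), two-sided; Bonferroni adjustment `min(1, m·p)` with m the
  number of requested comparisons.
* **Circular ROI**: a pixel belongs to the disc when its integer centre
  lies within `radius_px` of the ROI centre, boundary inclusive
  (a radius-4 disc holds 49 lattice pixels); out-of-image pixels are
  excluded from numerator and denominator, so corner ROIs average the
  in-bounds part only. The radius (default 4 px, the macro's "enlarge"
  argument) is the operational parameter; labelling a disc as adjacent to
  an enlarged one is a table annotation, not a geometric computation.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the analyses rest on:
narrowband ~200 Hz oscillation with genotype-dependent left–right phase
coupling, a distance-coded unimodal sensor with quantisation noise,
flight/rest alternation, binomial phenotype counts, and skewed positive
intensities. It does **not** model aerodynamics, thoracic resonance
mechanics, stroke-amplitude asymmetries between wings, sensor drift or
ambient-light interference, electronic sampling artefacts (interrupt
timing, channel multiplexing), or the spatial structure of real
micrographs. Passing tests therefore demonstrate that the *analysis*
recovers known ground truth under the assumed signal model — not that the
signal model captures every property of real recordings.

## Problem sizes and numerics

Synchrony properties are checked at 10 flies × 50 windows on 2-s
recordings; the headline simulation checks use single 10-s recordings at
10 kHz (100 000 samples), binomial coverage uses 2000 replicates at
n = 12, and oracle equivalences use 500–1000 random instances. These
sizes put Monte-Carlo error well inside the asserted margins while the
whole suite runs in a few seconds. Pearson r is computed in float64 with
a single centred pass; zero-variance windows are flagged rather than
propagating division by zero. All randomness flows from explicit integer
seeds; hypothesis-based property tests run derandomised.

## Known limitations

* The frequency estimator's band fold assumes the true beat lies at or
  below 300 Hz; it would halve a genuine >300 Hz oscillation.
* Bout detection assumes rest segments are variance-quiet; a sensor with
  strongly non-stationary noise would need a different baseline.
* The homogeneous-recording spectral classification depends on a
  narrowband-concentration threshold (50×) that separates oscillation
  from white noise by orders of magnitude in the simulated regime but is
  not calibrated against real hardware noise.
* With extreme locked-mode jitter (sd ≳ 1 rad) the doubled line carries
  only ~2% of the signal power; the pipeline still detects flight via
  the OU spectrum's concentrated sidebands, but a physically rougher
  jitter process might not be detected.
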