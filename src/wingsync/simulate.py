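"""Synthetic dual-wing reflectance recordings and myofibril phenotype fixtures.

The behavioural rig this module emulates records both wings of a tethered
fly with a pair of infrared proximity sensors, one per wing.  Each sensor
reports most strongly when the wing sits at a characteristic distance
(0.635 mm for the QRD1114 part) and reports nothing beyond its range
(3 mm), so a sinusoidal wing stroke that sweeps through the peak-response
distance produces a sensor signal dominated by *twice* the wing-beat
frequency.  The generator reproduces that geometry, ADC quantisation,
flight/rest bout structure and several left-right phase-coupling regimes,
so that the downstream synchrony analysis can be exercised with known
ground truth.

Two small tabular generators accompany it: per-image myofibril phenotype
counts (ruptured / frayed / enlarged Z-discs out of 10-15 myofibrils per
image) and per-Z-disc fluorescence intensities by disc class, the inputs
of the proportion and intensity statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "COUPLING_MODES",
    "DISC_CLASSES",
    "PHENOTYPE_CLASSES",
    "SimConfig",
    "Recording",
    "PhenotypeCount",
    "IntensitySample",
    "sensor_response",
    "simulate_recording",
    "simulate_phenotype_counts",
    "simulate_intensities",
]

COUPLING_MODES = ("locked", "drift", "intermittent", "no_flight")
PHENOTYPE_CLASSES = ("ruptured", "frayed", "enlarged")
DISC_CLASSES = ("intact", "ruptured", "enlarged", "adjacent_to_enlarged")

#: Sensor response sigma as a fraction of (max range - peak distance); the
#: Gaussian falls to ~1% of peak at the detection cutoff and is clipped to 0.
_SIGMA_FRACTION = 1.0 / 3.0

#: Floor (ms) applied to intermittent bout/rest durations so that every
#: generated bout is long enough for the default bout detector to resolve.
_MIN_SEGMENT_MS = 100.0

#: Correlation time (s) of the stationary phase perturbation in locked
#: modes: two beat periods at the default 200 Hz, so jitter is smooth on
#: the sample scale but decorrelates between analysis windows.
_JITTER_TAU_S = 0.010


@dataclass(frozen=True)
class SimConfig:
    """Generative parameterisation of one dual-wing recording.

    Parameters
    ----------
    beat_frequency_hz
        Wing-beat fundamental in Hz.  Tethered Drosophila beat at roughly
        200 Hz, the default.
    phase_offset_rad
        Systematic left-right phase offset, radians.
    phase_jitter_sd
        Phase perturbation sd in radians.  In ``locked`` (and the
        locked-style ``intermittent`` / ``no_flight``) modes each wing
        carries an independent stationary Ornstein-Uhlenbeck phase
        perturbation with this sd about the shared base phase, so the
        left-right relative phase stays bounded, as phase locking
        implies; in ``drift`` mode it is the per-sample increment sd of
        an independent Wiener process per wing, so the wings decohere
        over time.
    freq_mismatch_hz
        Constant left-right beat-frequency difference (right minus left).
    coupling_mode
        One of ``locked``, ``drift``, ``intermittent``, ``no_flight``.
    amplitude_mm, rest_distance_mm
        Wing-tip excursion about the mean wing-sensor distance.
    sensor_peak_mm, sensor_max_mm
        Distance of maximal sensor response and the detection cutoff.
    noise_sd
        Additive sensor noise sd in ADC counts, applied before quantisation.
    fs_hz
        Sampling rate; 10 kHz by default so a 5-ms analysis window holds
        50 samples.
    duration_s
        Recording length; ``duration_s * fs_hz`` must be a whole number.
    bout_on_s, bout_off_s
        Mean flight and rest bout durations for ``intermittent`` mode.
    adc_bits
        ADC resolution; output values span ``[0, 2**adc_bits - 1]``.
    seed
        Seed for the generator.  Left/right jitter, bout placement and
        sensor noise draw from independent substreams, so e.g. switching
        noise off does not move the bouts.
    """

    beat_frequency_hz: float = 200.0
    phase_offset_rad: float = 0.0
    phase_jitter_sd: float = 0.0
    freq_mismatch_hz: float = 0.0
    coupling_mode: str = "locked"
    amplitude_mm: float = 0.4
    rest_distance_mm: float = 0.635
    sensor_peak_mm: float = 0.635
    sensor_max_mm: float = 3.0
    noise_sd: float = 0.0
    fs_hz: float = 10_000.0
    duration_s: float = 1.0
    bout_on_s: float = 0.5
    bout_off_s: float = 0.5
    adc_bits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "beat_frequency_hz": self.beat_frequency_hz,
            "phase_offset_rad": self.phase_offset_rad,
            "phase_jitter_sd": self.phase_jitter_sd,
            "freq_mismatch_hz": self.freq_mismatch_hz,
            "amplitude_mm": self.amplitude_mm,
            "rest_distance_mm": self.rest_distance_mm,
            "sensor_peak_mm": self.sensor_peak_mm,
            "sensor_max_mm": self.sensor_max_mm,
            "noise_sd": self.noise_sd,
            "fs_hz": self.fs_hz,
            "duration_s": self.duration_s,
            "bout_on_s": self.bout_on_s,
            "bout_off_s": self.bout_off_s,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
        for name in ("beat_frequency_hz", "amplitude_mm", "sensor_peak_mm",
                     "sensor_max_mm", "fs_hz", "duration_s", "bout_on_s",
                     "bout_off_s"):
            if numeric[name] <= 0:
                raise ValueError(f"{name} must be positive, got {numeric[name]!r}")
        for name in ("phase_jitter_sd", "noise_sd"):
            if numeric[name] < 0:
                raise ValueError(f"{name} must be non-negative, got {numeric[name]!r}")
        if self.coupling_mode not in COUPLING_MODES:
            raise ValueError(
                f"coupling_mode must be one of {COUPLING_MODES}, got {self.coupling_mode!r}"
            )
        if self.sensor_peak_mm >= self.sensor_max_mm:
            raise ValueError("sensor_peak_mm must be smaller than sensor_max_mm")
        if self.fs_hz <= 2 * self.beat_frequency_hz:
            raise ValueError("fs_hz must exceed twice the beat frequency (Nyquist)")
        if not isinstance(self.adc_bits, (int, np.integer)) or self.adc_bits <= 0:
            raise ValueError(f"adc_bits must be a positive integer, got {self.adc_bits!r}")
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ValueError(
                f"duration_s * fs_hz must be a whole number of samples, got {n!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    @property
    def adc_full_scale(self) -> int:
        return 2 ** self.adc_bits - 1


@dataclass
class Recording:
    """Two-channel sampled reflectance signal.

    ``left`` and ``right`` are equal-length integer arrays in ADC counts;
    ``meta`` carries free-form labels plus, for simulated recordings, the
    generating parameters and the ground-truth flight-bout intervals
    (``meta["true_bouts"]``, half-open sample intervals).
    """

    fs_hz: float
    left: np.ndarray
    right: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left)
        self.right = np.asarray(self.right)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left and right must be 1-D arrays of equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    def __len__(self) -> int:
        return self.left.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz


@dataclass(frozen=True)
class PhenotypeCount:
    """Per-image myofibril phenotype counts.

    The affected-myofibril ratio for a class is the class count divided by
    ``n_total``, the number of myofibrils visible in the image.
    """

    image_id: str
    n_ruptured: int
    n_frayed: int
    n_enlarged: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"{self.image_id}: n_total must be positive")
        for name in ("n_ruptured", "n_frayed", "n_enlarged"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{self.image_id}: {name} must be non-negative")
            if value > self.n_total:
                raise ValueError(
                    f"{self.image_id}: {name}={value} exceeds n_total={self.n_total}"
                )


@dataclass(frozen=True)
class IntensitySample:
    """Mean gray value of one Z-disc ROI, labelled by disc class and genotype."""

    disc_id: str
    disc_class: str
    genotype: str
    mean_gray: float

    def __post_init__(self) -> None:
        if self.disc_class not in DISC_CLASSES:
            raise ValueError(
                f"disc_class must be one of {DISC_CLASSES}, got {self.disc_class!r}"
            )
        if not math.isfinite(self.mean_gray):
            raise ValueError(f"{self.disc_id}: mean_gray must be finite")


def sensor_response(distance_mm, peak_mm: float = 0.635, max_mm: float = 3.0):
    """Normalised reflectance-sensor response at a wing-sensor distance.

    A smooth unimodal curve: Gaussian in distance centred at ``peak_mm``,
    baseline-shifted so it reaches exactly zero at the detection cutoff
    ``max_mm`` and clipped to zero beyond.  Returns values in [0, 1].
    """
    distance_mm = np.asarray(distance_mm, dtype=float)
    sigma = _SIGMA_FRACTION * (max_mm - peak_mm)
    z = (distance_mm - peak_mm) / sigma
    tail = math.exp(-0.5 * ((max_mm - peak_mm) / sigma) ** 2)
    resp = (np.exp(-0.5 * z * z) - tail) / (1.0 - tail)
    resp = np.where(np.abs(distance_mm - peak_mm) >= (max_mm - peak_mm), 0.0, resp)
    return np.clip(resp, 0.0, 1.0)


def _ou_phase(rng: np.random.Generator, n: int, sd: float, fs_hz: float,
              tau_s: float = _JITTER_TAU_S) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck phase perturbation, sd radians.

    AR(1) discretisation with coefficient ``exp(-dt/tau)``; the process is
    started from its stationary law, so the perturbation sd equals ``sd``
    at every sample.  ``sd = 0`` returns zeros without consuming draws
    beyond the stream's ``n + 1`` normals, keeping streams aligned.
    """
    eps = rng.normal(0.0, 1.0, n + 1)
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = math.exp(-1.0 / (tau_s * fs_hz))
    innov_sd = math.sqrt(1.0 - a * a)
    # AR(1) via IIR filter; eps[0] seeds the stationary (unit-variance) start
    theta, _ = lfilter([innov_sd], [1.0, -a], eps[1:], zi=[a * eps[0]])
    return sd * theta


def _draw_bout_mask(config: SimConfig, rng: np.random.Generator):
    """Alternating flight/rest mask for intermittent mode plus ground truth."""
    n = config.n_samples
    floor = _MIN_SEGMENT_MS / 1000.0
    mask = np.zeros(n, dtype=bool)
    bouts: list[tuple[int, int]] = []
    pos = 0
    flying = True  # recordings start at the air-puff stimulus
    while pos < n:
        mean = config.bout_on_s if flying else config.bout_off_s
        # gamma(4) keeps durations away from zero; floored for detectability
        dur_s = max(floor, rng.gamma(4.0, mean / 4.0))
        seg = min(n, pos + int(round(dur_s * config.fs_hz)))
        if flying and seg > pos:
            mask[pos:seg] = True
            bouts.append((pos, seg))
        pos = seg
        flying = not flying
    return mask, bouts


def _single_cycle_mask(config: SimConfig, rng: np.random.Generator):
    """Sparse isolated single-beat cycles for no_flight mode."""
    n = config.n_samples
    period = max(1, int(round(config.fs_hz / config.beat_frequency_hz)))
    mask = np.zeros(n, dtype=bool)
    events: list[tuple[int, int]] = []
    n_events = rng.poisson(0.5 * config.duration_s)
    for start in sorted(rng.integers(0, max(1, n - period), size=n_events)):
        mask[start:start + period] = True
        events.append((int(start), int(start + period)))
    return mask, events


def simulate_recording(config: SimConfig) -> Recording:
    """Generate one dual-wing reflectance recording.

    The wing-sensor distance of wing *w* is
    ``d_w(t) = rest_distance + amplitude * sin(phi_w(t))``, mapped through
    :func:`sensor_response`, scaled to the ADC full range, noise-corrupted,
    and rounded (half-up) to integer ADC counts.  Phase evolution per
    ``coupling_mode``:

    * ``locked`` — both wings share the base phase; each receives an
      independent stationary Ornstein-Uhlenbeck phase perturbation (sd
      ``phase_jitter_sd``, correlation time 10 ms) and the right wing the
      constant ``phase_offset_rad``.
    * ``drift`` — phases evolve independently: random initial phases,
      independent Wiener jitter, and ``freq_mismatch_hz`` on the right.
    * ``intermittent`` — locked oscillation alternating with rest segments.
    * ``no_flight`` — rest level throughout except isolated single beat
      cycles.

    Deterministic given ``config.seed``.
    """
    n = config.n_samples
    ss = np.random.SeedSequence(config.seed)
    rng_l, rng_r, rng_bouts, rng_noise = [np.random.default_rng(s) for s in ss.spawn(4)]

    t = np.arange(n) / config.fs_hz
    base = 2.0 * math.pi * config.beat_frequency_hz * t
    mismatch = 2.0 * math.pi * config.freq_mismatch_hz * t

    if config.coupling_mode == "drift":
        jitter_l = np.cumsum(rng_l.normal(0.0, config.phase_jitter_sd, n))
        jitter_r = np.cumsum(rng_r.normal(0.0, config.phase_jitter_sd, n))
        phi_l = base + rng_l.uniform(0.0, 2.0 * math.pi) + jitter_l
        phi_r = base + mismatch + rng_r.uniform(0.0, 2.0 * math.pi) + jitter_r
    else:
        phi_l = base + _ou_phase(rng_l, n, config.phase_jitter_sd, config.fs_hz)
        phi_r = (base + mismatch + config.phase_offset_rad
                 + _ou_phase(rng_r, n, config.phase_jitter_sd, config.fs_hz))

    if config.coupling_mode == "intermittent":
        mask, true_bouts = _draw_bout_mask(config, rng_bouts)
    elif config.coupling_mode == "no_flight":
        mask, true_bouts = _single_cycle_mask(config, rng_bouts)
        true_bouts = []  # isolated cycles are not flight bouts
    else:
        mask = np.ones(n, dtype=bool)
        true_bouts = [(0, n)]

    full = float(config.adc_full_scale)
    channels = []
    for phi in (phi_l, phi_r):
        d = np.where(mask,
                     config.rest_distance_mm + config.amplitude_mm * np.sin(phi),
                     config.rest_distance_mm)
        analog = full * sensor_response(d, config.sensor_peak_mm, config.sensor_max_mm)
        analog = analog + rng_noise.normal(0.0, config.noise_sd, n)
        counts = np.clip(np.floor(analog + 0.5), 0.0, full).astype(np.int32)
        channels.append(counts)

    meta = {
        "coupling_mode": config.coupling_mode,
        "beat_frequency_hz": config.beat_frequency_hz,
        "seed": config.seed,
        "true_bouts": true_bouts,
        "config": config,
    }
    return Recording(fs_hz=config.fs_hz, left=channels[0], right=channels[1], meta=meta)


def simulate_phenotype_counts(
    n_images: int,
    p_affected: Mapping[str, float],
    totals_range: tuple[int, int] = (10, 15),
    seed: int = 0,
) -> list[PhenotypeCount]:
    """Draw per-image myofibril phenotype counts.

    Each image shows ``n_total`` myofibrils drawn uniformly from
    ``totals_range`` (inclusive; default 10-15, the typical per-image count).
    Every myofibril is independently assigned at most one phenotype class
    with the probabilities in ``p_affected`` (keys among ``ruptured``,
    ``frayed``, ``enlarged``), so each class count is binomial given the
    total and the class counts never exceed it.
    """
    if n_images < 0:
        raise ValueError("n_images must be non-negative")
    unknown = set(p_affected) - set(PHENOTYPE_CLASSES)
    if unknown:
        raise ValueError(f"unknown phenotype classes: {sorted(unknown)}")
    probs = np.array([float(p_affected.get(c, 0.0)) for c in PHENOTYPE_CLASSES])
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("phenotype probabilities must lie in [0, 1]")
    if probs.sum() > 1.0 + 1e-12:
        raise ValueError(
            f"per-myofibril class probabilities sum to {probs.sum():.3f} > 1"
        )
    lo, hi = int(totals_range[0]), int(totals_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError(f"totals_range must be a positive interval, got {totals_range!r}")

    rng = np.random.default_rng(seed)
    full_probs = np.append(probs, max(0.0, 1.0 - probs.sum()))
    full_probs /= full_probs.sum()
    records = []
    totals = rng.integers(lo, hi + 1, size=n_images)
    for i, total in enumerate(totals):
        counts = rng.multinomial(int(total), full_probs)
        records.append(PhenotypeCount(
            image_id=f"img{i:04d}",
            n_ruptured=int(counts[0]),
            n_frayed=int(counts[1]),
            n_enlarged=int(counts[2]),
            n_total=int(total),
        ))
    return records


def simulate_intensities(
    n_per_class: int,
    class_means: Mapping[str, float],
    class_sd: Mapping[str, float] | float = 0.0,
    seed: int = 0,
    genotype: str = "synthetic",
) -> list[IntensitySample]:
    """Draw per-disc mean-gray intensities by disc class.

    Values are log-normal: ``exp(Normal(log(mean), sd))`` per class, with
    ``sd`` on the log scale, so intensities are positive and ``sd = 0``
    returns the class mean exactly.  Deterministic given ``seed``.
    """
    if not class_means:
        raise ValueError("class_means must name at least one disc class")
    unknown = set(class_means) - set(DISC_CLASSES)
    if unknown:
        raise ValueError(f"unknown disc classes: {sorted(unknown)}")
    if n_per_class < 0:
        raise ValueError("n_per_class must be non-negative")
    if not isinstance(class_sd, Mapping):
        class_sd = {c: float(class_sd) for c in class_means}
    for cls, mean in class_means.items():
        if mean <= 0:
            raise ValueError(f"class mean for {cls!r} must be positive")
        if class_sd.get(cls, 0.0) < 0:
            raise ValueError(f"class sd for {cls!r} must be non-negative")

    rng = np.random.default_rng(seed)
    samples = []
    for cls in sorted(class_means):
        log_values = rng.normal(math.log(class_means[cls]),
                                class_sd.get(cls, 0.0), n_per_class)
        for j, lv in enumerate(log_values):
            samples.append(IntensitySample(
                disc_id=f"{cls}_{j:04d}",
                disc_class=cls,
                genotype=genotype,
                mean_gray=float(math.exp(lv)),
            ))
    return samples
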