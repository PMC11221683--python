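"""Classify wing-beat synchrony in simulated control and mutant-like flies.

Generates ten phase-locked "control" recordings and ten independently
drifting "mutant-like" recordings, runs the windowed Pearson pipeline
(flight-bout detection, 50 random 5-ms windows per fly, r > 0.5 means a
synchronized event), and prints the pooled synchronized-event proportion
with its exact binomial 95% confidence interval for each group.
"""

from wingsync import AnalysisParams, SimConfig, analyze_recording, \
    simulate_recording, summarize_events

groups = {
    "control (locked, low jitter)": dict(
        coupling_mode="locked", phase_jitter_sd=0.05, noise_sd=2.0),
    "mutant-like (drifting wings)": dict(
        coupling_mode="drift", phase_jitter_sd=0.02, freq_mismatch_hz=15.0,
        noise_sd=2.0),
}

for name, kwargs in groups.items():
    pool = []
    for fly in range(10):
        cfg = SimConfig(duration_s=2.0, seed=1000 + fly, **kwargs)
        pool += analyze_recording(simulate_recording(cfg),
                                  AnalysisParams(seed=2000 + fly))
    s = summarize_events(pool)
    print(f"{name}: {s.n_synchronized}/{s.n_events - s.n_degenerate} "
          f"synchronized = {s.proportion_synchronized:.3f} "
          f"(95% CI {s.ci_low:.3f}-{s.ci_high:.3f})")

# The control proportion sits near 1.0 (all windows tightly correlated);
# drifting wings fall well below 0.5 because the left-right phase sweeps
# through all offsets, and only near-zero relative phase gives r > 0.5.
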