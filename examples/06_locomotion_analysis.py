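"""Locomotion speed-trace analysis: segmentation and bimodal speed fit.

Generates a synthetic signed-speed trace at the reported local-search
statistics (forward ~93% of time at +260 um/s, brief backward excursions at
-308 um/s), segments it by sign, and fits the two speed modes back.
"""

from wormcircuit import (
    SyntheticBehaviorConfig,
    fit_speed_distribution,
    locomotion_summary,
    segment_locomotion,
    synthesize_speed_trace,
)

config = SyntheticBehaviorConfig(n_frames=100_000, seed=7)
trace = synthesize_speed_trace(config)
events = segment_locomotion(trace, dead_band=0.0)
summary = locomotion_summary(events)
fit = fit_speed_distribution(trace.speeds)

fwd, bwd = summary["states"]["forward"], summary["states"]["backward"]
print(f"trace: {len(trace)} frames at {trace.frame_rate:g} Hz "
      f"({summary['total_duration_s']:.0f} s)")
print(f"forward  : {100 * fwd['time_fraction']:5.2f}% of time, "
      f"{fwd['event_count']} events, mean duration {fwd['mean_duration_s']:.1f} s")
print(f"backward : {100 * bwd['time_fraction']:5.2f}% of time, "
      f"{bwd['event_count']} events, mean duration {bwd['mean_duration_s']:.1f} s")
print(f"fitted speed modes: forward {fit.mu_forward:+.1f} um/s "
      f"(sd {fit.sigma_forward:.1f}), backward {fit.mu_backward:+.1f} um/s "
      f"(sd {fit.sigma_backward:.1f})")
print(
    "\nThe two recovered centers match the generator within sampling error;\n"
    "forward events are an order of magnitude longer than backward ones while\n"
    "their absolute speeds stay comparable -- the signature of a strongly\n"
    "forward-biased two-attractor switch."
)
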