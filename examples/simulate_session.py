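"""Generate one synthetic imaging session and look at what it contains.

Builds a 100-trial two-whisker discrimination session with 30 axons from
the three thalamocortical classes, prints the trial mix, the behavioral
performance, and one axon's ground truth.
"""

import axoncal as ax

cfg = ax.SessionConfig(n_trials=100, seed=7)
pop = ax.PopulationConfig(n_axons=30)
trials, truth, segments = ax.generate_session(cfg, pop=pop, seed=7)

print("trial conditions:")
print(trials["condition"].value_counts().to_string())
print(f"\nsession performance (hits + correct rejections over stimulus "
      f"trials): {ax.session_performance(trials):.3f}")
print(f"segments emitted: {len(segments)} "
      f"({len(truth.axons)} ground-truth axons)")

spec = truth.axons[0]
print(f"\naxon 0: class={spec.axon_class}, true WSI={spec.true_wsi:+.2f}, "
      f"latency={spec.true_latency * 1000:.0f} ms, "
      f"{spec.n_segments} segment(s)")
print("A positive WSI means the axon prefers the C2 whisker; the latency is "
      "the delay from stimulus onset to the calcium event.")
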