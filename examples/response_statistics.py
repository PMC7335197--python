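"""Evoked-response significance, latency and whisker selectivity.

Per axon and condition, each post-stimulus time bin is z-tested over
trials; a response is significant when -log10(p) exceeds 10 in three
consecutive bins, its latency is the first bin above 5, and the whisker
selectivity index (WSI) contrasts the C2 and B2 response-window amplitudes.
"""

import axoncal as ax

cfg = ax.SessionConfig(n_trials=80, seed=11)
beh = ax.BehaviorConfig(p_lick={"C2": 0.0, "B2": 0.0, "none": 0.0})  # passive
pop = ax.PopulationConfig(n_axons=10)
trials, truth, segments = ax.generate_session(cfg, beh, pop, seed=11)

merged = ax.merge_segments(segments, ax.correlation_cluster(segments))
print("axon  class        true_wsi  est_wsi  significant  latency_ms  tuned")
for m in merged:
    spec = truth.axons[m.axon_id]
    tensor = ax.trial_zscore(ax.normalize_trace(m), trials, cfg)
    resp = ax.analyze_axon(tensor)
    pref = ("C2", False) if (resp.wsi or 0) >= 0 else ("B2", False)
    grp = resp.groups.get(pref)
    lat = f"{grp.latency * 1000:7.0f}" if grp and grp.latency is not None \
        else "      -"
    wsi = f"{resp.wsi:+.2f}" if resp.wsi is not None else "    -"
    print(f"{m.axon_id:4d}  {spec.axon_class:<12} {spec.true_wsi:+8.2f} "
          f"   {wsi}  {str(bool(grp and grp.significant)):>11} {lat}"
          f"  {resp.tuned}")
print("\n|WSI| >= 0.75 marks an axon as tuned to one whisker; estimated WSI "
      "tracks the ground truth and latencies recover the configured class "
      "offsets to about one 33 ms frame.")
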