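"""Screen a predicted track set for mislabels needing re-annotation.

A jump is a displacement of more than 200 px between consecutive frames —
the signature of the detector latching onto a waterer, manure pile or shoe.
A missing run is >30 consecutive frames without a prediction for a marker
expected to be visible.  The report is the hand-off artifact for visual
inspection and targeted re-annotation.
"""

import stalltrack as st

# the screening statistic on a worked pair of frames:
stat, disp = st.jump_statistic(100, 100, 1, 400, 100, 2)
print(f"frame 1 -> 2, (100,100) -> (400,100): statistic {stat:.0f} px^2, "
      f"displacement {disp:.0f} px  (> 200 px, flagged)")

scenario = st.build_scenario({"n_frames": 10_000, "seed": 3})
truth, _ = st.simulate_tracks(scenario)
tracks, log = st.degrade_to_predictions(truth, scenario.artifacts, 4, scenario.geometry)

wp, report = st.qc_report(tracks, truth, video_id="demo")
injected = sum(1 for e in log if e["type"] == "jump")
print(f"\ninjected teleports: {injected}; flagged segments: {len(report)}")
print(f"wrongly predicted (WP) frames per marker: {wp}")
print(report.head(5).to_string(index=False))
# each jump row carries both the squared-pixel screening statistic and the
# Euclidean displacement that was thresholded against the 200-px rule.
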