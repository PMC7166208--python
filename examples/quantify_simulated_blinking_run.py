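"""Simulate a forceful-blinking run with slice leakage and quantify it.

Generates a desk-scale synthetic 4D run (48x48x16 grid, 200 volumes of
the 20 s-on / 20 s-off blinking paradigm) in which 20% of the eye-signal
fluctuation leaks to each predicted alias disk, places two control disks
away from the predictions, and computes the on-vs-off artefact-intensity
statistic for every region.
"""

import warnings

import smsleak as sl

warnings.filterwarnings("ignore")  # anterior disks clip the small FOV edge

result = sl.simulate(sl.reduced_scenario(seed=1))
controls = sl.control_masks(result.geom, result.alias_locations,
                            result.brain_mask, n=2, min_distance=8, seed=1)

kinds = [loc.kind.value for loc in result.alias_locations] + ["control"] * 2
report = sl.region_report(result.data, result.alias_masks + controls,
                          result.design, kinds=kinds)
print(report.to_string(index=False))

alias = report[report.kind != "control"]["difference_pct"]
ctrl = report[report.kind == "control"]["difference_pct"]
print(f"\nweakest alias-region difference: {alias.min():.1f}%")
print(f"strongest control difference:    {ctrl.max():.1f}%")
print("Positive differences mean larger volume-to-volume signal change "
      "during blinking blocks; injected alias regions separate cleanly "
      "from controls.")
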