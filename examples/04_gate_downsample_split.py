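"""Gating trees, balanced downsampling, and cell-wise splitting.

Gates never delete events — membership is a boolean tag per event, so a
whole gating strategy composes by ANDing child tags with their parent.
Downsampling then tags a subset where every group, and every sample
within a group, contributes equally; splitting divides each sample's
tagged cells into A/B halves for training/validation designs.
"""

import numpy as np

import cytopipe as cp

dataset, _ = cp.simulate_dataset(cp.benchmark_design(seed=1, n_events=5000))

# gate the M1-bright cells, then the M2-bright subset of those
g1 = cp.Gate("M1_pos", "interval", ("M1",), (2.0, 10.0))
g2 = cp.Gate("M1M2_pos", "rectangle", ("M1", "M2"), (2.0, 10.0, 2.0, 10.0),
             parent="M1_pos")
dataset = cp.apply_gates(dataset, [g1, g2])
freq = cp.gate_frequencies(dataset, "M1M2_pos", parent="M1_pos")
print("M2+ fraction of the M1+ population, per sample:")
print(freq[["sample_id", "group", "n_in", "n_parent", "percent"]]
      .round(1).to_string(index=False))

down = cp.downsample_balanced(dataset, base_tag="gate:M1_pos", seed=1)
counts = {s.sample_id: int(s.tags["downsampled"].sum()) for s in down}
print(f"\nbalanced downsample of the M1+ population: {counts}")
print("(equal per sample within a group; groups contribute equally)")

split = cp.split_dataset(down, fraction=0.5, seed=1)
s = split.samples[0]
print(f"\nsplit of {s.sample_id}: "
      f"A={int(s.tags['split:A'].sum())}, B={int(s.tags['split:B'].sum())}, "
      f"total events untouched: {s.n_events}")
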