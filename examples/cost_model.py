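"""Predict per-node accelerator time with the analytic pipeline model.

A fixed-latency pipeline processes one character per cycle after its
startup latency, so the average time per tree node is
(L_nonroot*lambda + lambda*c)(1-r) + (L_root*lambda + lambda*c)r, with lambda the
clock period, c the sequence length, and r the fraction of node
evaluations that engage the root (log-likelihood) pipeline. The table
prints the prediction for the built-in benchmark datasets on both device
profiles.
"""

from plfkit.costmodel import DatasetParams, V2P, avg_node_time, round_us, table3_report

print(table3_report().to_string(index=False))

t = avg_node_time(V2P, DatasetParams("custom", 5000, 0.02))
print(f"\ncustom dataset (c=5000, r=0.02) on the 165 MHz profile: "
      f"{round_us(t):.1f} us per node")
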