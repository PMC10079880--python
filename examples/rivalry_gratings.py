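"""Binocular rivalry with orthogonal gratings, plus percept reconstruction.

Runs the two-pool network for 12 s driven by a horizontal grating (pool 1)
and a vertical grating (pool 2), segments the dominance metric, and
reconstructs the dominant stimulus from each dominance window by orthogonal
matching pursuit in the 2-D DCT basis.
"""

import numpy as np

from rivalnet import ModelParams
from rivalnet.experiments import run_rivalry

run = run_rivalry(ModelParams(), duration=12000.0, seed=1, reconstruct=True)

print("dominance segments (pool, start ms, duration ms):")
for s in run.segments:
    tag = " transient" if s.is_transient else ""
    print(f"  pool {s.pool}  {s.t_start:7.0f}  {s.duration:6.0f}{tag}")

st = run.stats
print(f"\nalternation rate: {st.alternation_rate * 1000:.2f} switches/s; "
      f"predominance pool1/pool2: {st.predominance[0]:.2f}/"
      f"{st.predominance[1]:.2f}")

print("\nper-window percept reconstruction error ||p - p_recon|| / ||p||:")
for r in run.reconstructions:
    tag = " transient" if r.is_transient else ""
    print(f"  segment {r.segment_id} (pool {r.pool}): "
          f"{r.relative_error:.3f}{tag}")
print("Errors well below 1 mean the dominant grating is read out almost "
      "perfectly from the downstream spiking activity alone.")
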