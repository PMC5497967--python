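"""Remove ventricular far-field QRS-T complexes by template subtraction.

Detects R peaks on the surface-ECG reference, averages the QRS-T complex
across beats, and subtracts the per-channel scaled template at every
beat.  Because the data are synthetic, the clean ground truth is known
and the residual error can be reported exactly.
"""

import numpy as np

from afnet import (
    SimulationConfig,
    add_ventricular_farfield,
    generate_basket_layout,
    generate_planted_network,
    remove_ventricular_farfield,
    simulate_coupled_af,
)

layout = generate_basket_layout(4, 4)
truth = generate_planted_network(16, "matching", coupling=0.6, seed=2)
cfg = SimulationConfig(duration_s=30.0, seed=2)
clean = simulate_coupled_af(layout, truth, cfg)
contaminated = add_ventricular_farfield(clean, cfg)

recovered, peaks = remove_ventricular_farfield(
    contaminated.recording, contaminated.ecg
)
print(f"detected {len(peaks)} beats "
      f"(truth placed {len(contaminated.r_peak_samples)})")

before = np.sqrt(np.mean((contaminated.recording.data - clean.data) ** 2))
after = np.sqrt(np.mean((recovered.data - clean.data) ** 2))
atrial_rms = np.sqrt(np.mean(clean.data**2))
print(f"ventricular RMS before subtraction: {before:.4f}")
print(f"residual RMS after subtraction:     {after:.4f} "
      f"({100 * after / atrial_rms:.1f}% of the atrial signal)")
# A residual of a few percent means the far field no longer dominates
# pairwise mutual information between channels.
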