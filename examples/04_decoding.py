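"""Frame-by-frame decoding of stimulus detection (Hit vs Miss).

Simulates a balanced session, trains one L2-logistic classifier per
peri-stimulus frame with nested cross-validation, and compares the true
curves to the shuffled-label chance baseline. Decoding rises above chance
only after stimulus onset; pre-stimulus frames carry no information.
"""

import numpy as np

from tactile2p import decoding as dc
from tactile2p import traces as tr
from tactile2p.config import SimConfig
from tactile2p.synth import simulate_session, wt_mouse

cfg = SimConfig(n_trials=100, go_fraction=1.0, n_neurons_range=(40, 40),
                timeout_rate=0.0)
session = simulate_session(cfg, wt_mouse(threshold_um=7.0),
                           np.random.default_rng(4), n_neurons=40)

dff, ok = tr.preprocess(session.traces)
aligned = tr.zscore_align(dff, session.trial_table, session.traces.frame_rate_hz,
                          celltype=session.traces.celltype, neuron_ok=ok)

res = dc.decode_session(aligned, np.random.default_rng(5))
print(f"balanced trials: {res.n_trials}, neurons: {res.n_neurons}")
print(f"stimulation window (0-500 ms):")
print(f"  true accuracy     {dc.window_average(res, dc.STIM_WINDOW_MS):.3f}")
print(f"  shuffled accuracy "
      f"{dc.window_average(res, dc.STIM_WINDOW_MS, 'shuffled_accuracy'):.3f}")
print(f"pre-stimulus window (-200-0 ms):")
print(f"  true accuracy     {dc.window_average(res, dc.PRESTIM_WINDOW_MS):.3f}")
print(f"  shuffled accuracy "
      f"{dc.window_average(res, dc.PRESTIM_WINDOW_MS, 'shuffled_accuracy'):.3f}")

# Cell-type-restricted decoders.
pyr = dc.decode_session(aligned, np.random.default_rng(6),
                        celltype_filter=tr.PYRAMIDAL, with_shuffled=False)
inh = dc.decode_session(aligned, np.random.default_rng(7),
                        celltype_filter=tr.INTERNEURON, with_shuffled=False)
print(f"pyramidal-only accuracy  {dc.window_average(pyr, dc.STIM_WINDOW_MS):.3f}")
print(f"interneuron-only accuracy {dc.window_average(inh, dc.STIM_WINDOW_MS):.3f}")
# Stimulation-window accuracy well above the ~0.5 shuffled baseline shows
# that detection is decodable from population activity frame by frame.
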