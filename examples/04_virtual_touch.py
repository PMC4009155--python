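"""Emulate a natural touch with optimized microstimulation.

Trains an inverse model (neural response -> stimulation amplitudes) on the
response to randomly patterned microstimulation, clones it as the
controller, and runs filtered-error adaptive inverse control toward the
response evoked by a natural touch at one skin site.  The optimized pulse
train - a "virtual touch" - is then scored by how much the evoked response
resembles the matched-site target versus a different site's target.
"""

import numpy as np

import spikefield as sf

result = sf.virtual_touch_trial(seed=0)

err = result.mean_abs_error
print(f"mean |filtered error| per epoch: {np.round(err, 3)}")
print(f"  -> epoch 5 vs epoch 1: {err[-1]:.3f} vs {err[0]:.3f} "
      f"({'converged' if result.converged else 'not converged'})")
print(f"delivered pulses: {result.n_pulses} (all within [8, 30] uA, "
      ">=10 ms apart per channel, one channel at a time)")
print(f"binned CC vs matched-site target:   {result.matched_cc:+.4f}")
print(f"binned CC vs mismatched-site target: {result.unmatched_cc:+.4f}")
peak = result.correlogram_lags[int(np.argmax(result.correlogram))]
print(f"event-locked cross-correlogram peak at lag {peak} (5 ms bins)")
print(
    "\nA higher matched-site correlation means the virtual touch carries "
    "site identity;\na peak at lag 0 means the controlled response is "
    "time-locked to the target."
)
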