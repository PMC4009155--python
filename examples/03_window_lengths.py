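"""Choose analysis window lengths from the data's autocorrelation.

The analysis window for each modality should cover the stimulus-evoked
response and no more.  The criterion: the smallest lag beyond which the
sample autocorrelation stays inside the +-2 SE confidence band of zero
(the SE accumulates the earlier coefficients, so the band widens for
strongly autocorrelated signals).
"""

import numpy as np

import spikefield as sf
from spikefield.decoding import autocorr, autocorr_bounds, binned_counts

# Simulate a touch experiment with a clean, transient response so each
# modality's own timescale is visible: low LFP noise (the evoked damped
# deflection dominates) and mostly onset-locked spiking.
cfg = sf.SyntheticPlantConfig(lfp_noise_sd=2.0, sustained_fraction=0.15)
stim = sf.generate_touch_stimulus(30.0, seed=2)
rec = sf.simulate_plant(stim, cfg, seed=2)

# LFP: per-channel autocorrelation averaged over channels (1 kHz sampling).
est_lfp = sf.estimate_window_length(rec.lfp, max_lag=60, sample_period=1.0)
print(f"LFP window length: {est_lfp.length_ms:.0f} ms "
      f"(converged={est_lfp.converged})")

# Spikes: 1 ms binned counts, pooled the same way.
counts = binned_counts(rec.spikes, rec.n_units, rec.duration_s, bin_ms=1.0)
est_spk = sf.estimate_window_length(counts.T, max_lag=60, sample_period=1.0)
print(f"spike window length: {est_spk.length_ms:.0f} ms "
      f"(converged={est_spk.converged})")

rho = autocorr(rec.lfp, 10)
lo, hi = autocorr_bounds(rho, rec.lfp.shape[0], 5)
print(f"\nLFP rho_1..rho_5 = {np.round(rho[1:6], 3)}; "
      f"95% zero band at lag 5: +-{hi:.4f}")
print(
    "\nThe LFP stays correlated for tens of ms (the damped evoked "
    "deflection), while\nspike-count correlations die out within about the "
    "evoked-burst width - which is\nwhy the two modalities get different "
    "window lengths.  The estimate tracks what\ndominates the signal: "
    "heavy broadband noise shortens the LFP's apparent\ntimescale, and "
    "strong sustained firing lengthens the spikes'."
)
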