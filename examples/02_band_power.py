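"""Per-epoch multitaper band power with global-spectrum normalisation.

Simulates one session of epoched EEG, estimates alpha/theta/beta power per
1.8 s epoch (3 DPSS tapers, normalised by mean 1-40 Hz power, pooled over
the right occipitoparietal channels), and shows how well each band tracks
the latent state that modulates only the alpha amplitude.
"""

import numpy as np

from dyncouple import SimConfig, simulate_eeg, simulate_latent_state
from dyncouple.eeg import DEFAULT_BANDS, multi_band_power_series

config = SimConfig()
latent = simulate_latent_state(306, cutoff_hz=0.02, tr=1.8, seed=3)
eeg = simulate_eeg(latent, config, seed=4)

series = multi_band_power_series(eeg, list(DEFAULT_BANDS.values()))
print("pooled channels:", ", ".join(series["alpha"].pooled_channels))
print(f"{'band':>6} {'mean power':>11} {'corr with latent':>17}")
for name, ps in series.items():
    r = np.corrcoef(ps.values, latent)[0, 1]
    print(f"{name:>6} {ps.values.mean():11.3f} {r:17.3f}")
# Alpha power is dimensionless (normalised by the global spectrum) and
# correlates strongly with the latent state; theta/beta fluctuate on their
# own and should show only weak, incidental correlation.
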