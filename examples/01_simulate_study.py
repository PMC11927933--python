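"""Simulate a small EEG-fMRI stimulation study with known ground truth.

Builds a 2-subjects-per-group pre/post study in which a slow latent state
drives both the vPCC-lAG / vPCC-rAG BOLD correlation and the occipitoparietal
alpha amplitude (active-post sessions only), and prints what was generated.
"""

from dyncouple import SimConfig, simulate_study

config = SimConfig(n_subjects_per_group=2, seed=42)
bundle = simulate_study(config)

print("design table:")
print(bundle.design.to_string(index=False))

entry = bundle.entries[("A01", "post")]
print(f"\nBOLD: {entry.bold.n_trs} TRs x {entry.bold.n_rois} ROIs "
      f"(TR = {entry.bold.tr} s)")
print(f"EEG:  {entry.eeg.n_channels} channels x {entry.eeg.n_epochs} epochs "
      f"x {entry.eeg.n_samples} samples ({entry.eeg.fs} Hz)")

truth = entry.truth
rho = truth.true_rho[("vPCC", "lAG")]
print(f"\nground-truth vPCC-lAG correlation: mean {rho.mean():.3f}, "
      f"range [{rho.min():.3f}, {rho.max():.3f}]")
print(f"injected coupling sign in this session: "
      f"{truth.true_coupling_sign[('vPCC', 'lAG')]:+d}")
# +1 means the latent state raises BOLD connectivity and alpha power together,
# so the downstream analysis should find positive FC-power coupling here.
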