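"""Extract the 330-column band-power feature table from EEG-like segments.

Builds a synthetic 30-channel, 3-s, 128-Hz segment set in which drowsy
segments carry stronger theta activity and alert segments stronger beta,
then runs the feature extraction: per channel, theta/alpha/beta Welch band
powers plus seven band-power ratios; per group (frontal, temporal, all),
the member-channel means.
"""

import fplselect as fp

segments = fp.make_segments(fp.SignalSpec(n_segments=40, seed=0))
features = fp.extract_features(segments)

print(f"segments: {segments.data.shape}  (n_segments, channels, timepoints)")
print(f"feature table: {features.n_samples} x {features.n_features}")
print("first columns:", features.feature_names[:3])
print("group columns:", features.feature_names[-3:])

# the planted theta multiplier for drowsy segments shows up directly
drowsy = features.labels == 1
col = features.select(["Fz__theta_psd"]).values[:, 0]
print(f"mean Fz theta power  drowsy: {col[drowsy].mean():8.2f}  "
      f"alert: {col[~drowsy].mean():8.2f}")
# Expected: 330 columns ((30 channels + 3 groups) x 10 features) and a
# clearly higher drowsy-class theta power.
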