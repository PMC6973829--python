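"""Morlet band-energy features at the four spatial scales.

One epoch is transformed with complex Morlet wavelets (40 log-spaced
frequencies, 1-80 Hz), squared magnitudes are averaged within canonical
bands, over sensors at a chosen scope, and over L temporal segments.
"""

from megstates import GenConfig, extract_epochs, generate_block, generate_layout
from megstates.features import (SENSOR_BANDS, extract_features, psd_features,
                                ward_cluster_sensors)

cfg = GenConfig(seed=3, n_sensors=64, n_motor_excluded=12)
layout = generate_layout(64, 12, seed=3)
layout = layout.with_clusters(ward_cluster_sensors(layout, 10))
block = generate_block(layout, "SFMC", cfg)
epoch = extract_epochs(block, 1200).epochs[0]

for scope in ("global", "left-hemi", "right-hemi", "local-10"):
    fv = extract_features(epoch, layout, scope, SENSOR_BANDS, L=4)
    print(f"{scope:10s}: {len(fv):4d} features "
          f"({len(set(ix[1] for ix in fv.index))} elements x 4 bands x 4 segments)")
# 16 / 16 / 16 / 160 — the dimensions the cross-validated models consume.

psd = psd_features(epoch, layout)
print(f"psd-local : {len(psd):4d} features (10 clusters x 4 bands, no segments)")
print("\nfirst local coordinates:", fv.index[:3])
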