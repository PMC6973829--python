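"""Cut labelled transition/maintenance epochs around button presses.

A transition epoch is the T ms window before each press, a maintenance
epoch the T ms window after it.  Events whose windows collide with a
neighbouring event (maintenance overlapping the next transition) are
rejected in pairs, keeping the two classes balanced.
"""

from megstates import GenConfig, extract_epochs, generate_block, generate_layout
from megstates.epochs import epochs_manifest, maintenance_subwindows

cfg = GenConfig(seed=2, n_sensors=32, n_motor_excluded=6, subject_rate_sigma=0.0)
layout = generate_layout(32, 6, seed=2)
block = generate_block(layout, "NCC", cfg)

for T in (600, 1200, 1800):
    es = extract_epochs(block, T)
    print(f"T = {T:4d} ms: {len(block.events)} events -> "
          f"{es.count('transition')} retained pairs")
# Longer windows reject more events: the overlap predicate is monotone in T.

es = extract_epochs(block, 1200)
print("\nepoch manifest (first rows):")
print(epochs_manifest(es).head(6).to_string(index=False))

offsets = maintenance_subwindows(1200, 100, 1800)
print(f"\ntemporal-evolution offsets (1200/100/1800): {offsets}")
# Seven shifted maintenance subwindows cover the press-to-1800 ms zone.
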