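"""Compute the four entropy measures on one epoch and see the state contrast.

Lower entropy = more regular signal. Fatigue-state epochs on a planted
electrode are dominated by narrowband rhythms, so all four measures drop
relative to the normal state.
"""

import entrofuse as ef

spec = ef.desk_spec(seed=0, effect_size=0.8, fs=256.0, duration_s=10.0)
normal = ef.preprocess_recording(ef.generate_recording("sub01", "normal", spec))
fatigue = ef.preprocess_recording(ef.generate_recording("sub01", "fatigue", spec))

ch = spec.channel_names.index("T6")  # a planted electrode
print(f"electrode T6, first 1 s epoch, m=2, r=0.2*SD")
print(f"{'measure':>8} {'normal':>8} {'fatigue':>8}")
for name, fn in [
    ("PE", lambda x: ef.spectral_entropy(x, spec.fs)),
    ("AE", ef.approximate_entropy),
    ("SE", ef.sample_entropy),
    ("FE", ef.fuzzy_entropy),
]:
    vn = fn(normal.epochs[0, ch])
    vf = fn(fatigue.epochs[0, ch])
    print(f"{name:>8} {vn:8.3f} {vf:8.3f}")

# Full fusion: every channel contributes its four measures, concatenated
# channel-major, then min-max normalized to [-1, 1] per subject.
pooled = ef.EpochSet.concat([normal, fatigue])
fm = ef.minmax_normalize(ef.extract_feature_matrix(pooled))
print(f"\nfused feature matrix: {fm.n_epochs} epochs x {fm.n_features} features "
      f"({len(spec.channel_names)} channels x 4 measures)")
print(f"value range after normalization: [{fm.values.min():.2f}, {fm.values.max():.2f}]")
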