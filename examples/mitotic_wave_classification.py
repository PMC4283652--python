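"""Classifying mitotic-wave geometry from division-onset times.

The wild-type syncytial embryo divides as two metachronous waves starting
at both poles (onset latest mid-embryo: a tent profile over axis position);
mutant embryos often show a single wave crossing from one pole (a line).
The classifier fits both models by least squares and picks the lower
residual sum of squares.
"""

from tfiihkit import defects as dfx, synthetic as syn

for mode in ("bidirectional", "unidirectional"):
    params = syn.WaveSimParams(
        mode=mode, wave_speed=60.0, onset_noise_sd=3.0, n_positions=12,
        origin_pole="posterior",
    )
    onsets = syn.simulate_wave_onsets(params, seed=4)
    w = dfx.classify_wave(
        onsets["position"].to_numpy(), onsets["onset_time_s"].to_numpy()
    )
    print(
        f"simulated {mode:14s} -> classified {w.classification:14s} "
        f"(origin {w.origin_pole}, speed {w.wave_speed:.1f} s/egg-length, "
        f"RSS tent={w.rss['bidirectional']:.1f} line={w.rss['unidirectional']:.1f})"
    )
print(
    "\nWave speed is seconds per normalized egg length; the winning model's "
    "RSS is markedly lower when onset noise is small relative to the wave "
    "traversal time."
)
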