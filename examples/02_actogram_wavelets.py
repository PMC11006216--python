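"""Decompose one woman's actogram and detect her oscillation wavelets.

Generates a series with a superimposed 3-day, 6-cycle oscillation plus a
phase jump, builds the normalized actogram (cumulative deviation from her
mean period), splits it into a 12-cycle trend and a 3-12-cycle band-pass
component, and lists the detected wavelets with their context labels.
"""

import numpy as np

from infradian import (
    SimulationParams,
    build_actogram,
    classify_wavelets,
    detect_wavelets,
    flag_large_amplitude,
    generate_series,
    render_actogram,
)

params = SimulationParams(
    mu=28, sigma=0.8, osc_amplitude=3, osc_period=6, ar1=0,
    jump_prob=0.03, jump_magnitude=14, n_cycles=60, seed=11,
)
series = generate_series(params, woman_id="example")
acto = build_actogram(series)

print(f"reference period (mean cycle length): {acto.reference_period:.2f} d")
print(f"final cumulative offset: {acto.offsets[-1]:.2e} d (always 0)")

wavelets = detect_wavelets(acto.trend, acto.band, min_duration=4)
wavelets = classify_wavelets(wavelets, series, jump_threshold=5.0, actogram=acto)
n_large, wavelets = flag_large_amplitude(wavelets, threshold=3.0)

print(f"{len(wavelets)} wavelets of >= 4 cycles; {n_large} with amplitude >= 3 d")
for w in wavelets:
    print(f"  cycles {w.start_index:2d}-{w.end_index:2d}  duration {w.duration} "
          f"amplitude {w.amplitude:.2f} d  [{w.context}]")

grid = render_actogram(acto)
print("\nraster (one row per cycle, * = onset position modulo the period):")
print("\n".join(grid[:12]))
# Wavelet durations cluster at the injected 6-cycle period and amplitudes
# near 3 d; wavelets starting within two cycles of a jump are labelled
# after_jump, the rest stable.
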