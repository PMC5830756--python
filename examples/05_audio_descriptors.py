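"""Audio envelope descriptors for pulsed vs non-pulsed performance audio.

Synthesizes a metrically regular click-train performance (132 bpm) and a
sparse free-improvisation-style event stream, then compares their envelope
descriptors: tempo, event density and pulse clarity.
"""

import numpy as np

from duetsync import (
    event_density,
    extract_envelope,
    pulse_clarity_simple,
    tempo_estimate,
)
from duetsync.simulate import nonpulsed_config, pulsed_config, simulate_audio

for name, cfg in [
    ("pulsed (132 bpm click train)", pulsed_config(duration_s=40.0, seed=0)),
    ("non-pulsed (sparse events)", nonpulsed_config(duration_s=40.0, seed=0)),
]:
    samples, sr = simulate_audio(cfg)
    env = extract_envelope(samples, sr)
    tempo = tempo_estimate(env)
    dens = event_density(env, peak_threshold=0.25 * env.values.max())
    clarity = float(np.median(pulse_clarity_simple(env).values))
    tempo_str = f"{tempo:6.1f} bpm" if np.isfinite(tempo) else "   n/a"
    print(f"{name}:")
    print(f"  tempo estimate: {tempo_str}   event density: {dens:.2f} /s   "
          f"median pulse clarity: {clarity:.2f}")
print("A regular beat shows up as high pulse clarity (autocorrelation peak of")
print("the onset envelope); the sparse stream has no stable periodicity.")
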