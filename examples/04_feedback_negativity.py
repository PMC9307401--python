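"""Medial-frontal feedback negativity: loss vs gain at Fz, and its scalp map.

About 232 ms after the outcome is revealed, the frontal-midline EEG
separates by outcome valence; the loss-minus-gain difference amplitude
(delta) grows with the stake ratio E.
"""

import numpy as np

from prestim import (
    EffectSpec,
    ExperimentConfig,
    delta_amplitude,
    generate_session,
    mfn_latency,
    mfn_result,
    preprocess_session,
    topomap,
)

config = ExperimentConfig(left_value=35, n_trials=300, seed=9)
effects = EffectSpec(loss_amplitude_uv=0.52, gain_amplitude_uv=2.04)
raw, events, truth = generate_session(config, effects)
result = preprocess_session(raw, events)

loss = result.evokeds[("feedback", "loss")]
gain = result.evokeds[("feedback", "gain")]

lat = mfn_latency(loss, gain)
res = mfn_result(loss, gain, latency=lat.latency)
print(f"injected: component at +{truth.mfn_latency:g} ms, delta {truth.delta:.2f} uV")
print(f"detected latency: {lat.latency:.0f} ms after feedback")
print(f"amplitudes at that latency: loss {res.loss_amplitude:+.2f} uV, "
      f"gain {res.gain_amplitude:+.2f} uV -> delta {res.delta:.2f} uV")
print(f"delta_amplitude(0.52, 2.04) = {delta_amplitude(0.52, 2.04):.2f} uV "
      "(the published-style arithmetic)")

diff = loss.copy()
diff.data = loss.data - gain.data
topo = topomap(diff, lat.latency, raw.montage_positions)
print(f"scalp map at +{topo.latency:.0f} ms: "
      f"{np.isfinite(topo.grid).sum()} raster points inside the head circle; "
      "plot it with prestim.erpstats.plot_topomap(topo, path='mfn_map.png')")
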