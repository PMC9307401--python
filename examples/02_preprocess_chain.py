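"""Run the preprocessing chain on a simulated session, stage by stage.

Continuous DC removal, blink labelling on VEOG, epoch extraction around the
decision and feedback markers, per-epoch baseline correction, +/-100 uV
amplitude rejection, per-condition averaging, zero-phase 30 Hz low-pass and
common average reference.
"""

import numpy as np

from prestim import (
    EffectSpec,
    ExperimentConfig,
    detect_blinks,
    generate_session,
    preprocess_session,
)

config = ExperimentConfig(left_value=35, n_trials=60, seed=7)
raw, events, truth = generate_session(config, EffectSpec())

blinks = detect_blinks(raw)
print(f"{len(blinks)} blink intervals labelled on VEOG (|VEOG| > 100 uV)")

result = preprocess_session(raw, events)
for lock in ("decision", "feedback"):
    kept = len(events) - result.n_rejected[lock]
    print(f"{lock}-locked epochs: kept {kept}/{len(events)}")

gain = result.evokeds[("feedback", "gain")]
loss = result.evokeds[("feedback", "loss")]
k = np.argmin(np.abs(gain.times - truth.mfn_latency))
print(f"Fz at +{truth.mfn_latency:g} ms: gain {gain.channel('Fz')[k]:+.2f} uV "
      f"(injected {truth.gain_amplitude:+.2f}), "
      f"loss {loss.channel('Fz')[k]:+.2f} uV (injected {truth.loss_amplitude:+.2f})")
print("with only ~30 trials per condition the averages still carry ~0.7 uV of")
print("residual noise; the full 300-trial design brings that down to ~0.25 uV")
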