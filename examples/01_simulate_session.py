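"""Simulate one gambling-task EEG session and look at its ground truth.

A session is one 15-minute block of 3-second trials: the subject picks the
left (large bet X) or right (small bet 5) square, and one second later the
squares turn green (gain) or red (loss) with equal probability.  Here we
generate a short 30-trial session to keep the demo fast.
"""

import numpy as np

from prestim import EffectSpec, ExperimentConfig, generate_session

config = ExperimentConfig(left_value=25, n_trials=30, seed=42)
effects = EffectSpec()  # the default study-like effect structure
raw, events, truth = generate_session(config, effects)

print(f"reward parameter E = {config.E:g}  (left {config.left_value} / right {config.right_value})")
print(f"recording: {raw.n_channels} channels x {raw.duration:.0f} s at {raw.sampling_rate:g} Hz")
print(f"trials: {len(events)} (gain on {sum(e.feedback == 'gain' for e in events)})")
print(f"blinks injected: {truth.blink_times.size}, bad blocks: {len(truth.bad_block_intervals)}")
print(f"ground truth: divergence onset {truth.divergence_onset:g} ms before the decision,")
print(f"  feedback component at +{truth.mfn_latency:g} ms with loss {truth.loss_amplitude:+.2f} uV,")
print(f"  gain {truth.gain_amplitude:+.2f} uV at Fz  ->  delta = {truth.delta:.2f} uV")
print(f"peak |VEOG| = {np.abs(raw.get_channel('VEOG')).max():.0f} uV (blinks exceed 100 uV)")
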