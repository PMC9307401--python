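"""Prestimulus time (PT): when do the two choice waveforms last intersect?

Before the subject presses a button, the frontal-midline EEG of upcoming
large-bet (left) choices turns more negative than that of small-bet (right)
choices.  PT is the time before the decision at which the two condition
averages last cross and stay separated through the button press.
"""

import numpy as np

from prestim import (
    EffectSpec,
    ExperimentConfig,
    compute_pt,
    generate_session,
    max_separation_time,
    preprocess_session,
)

config = ExperimentConfig(left_value=50, n_trials=300, seed=3)
effects = EffectSpec(divergence_onset_ms=178.0)  # high-stake block
raw, events, truth = generate_session(config, effects)
result = preprocess_session(raw, events)

left = result.evokeds[("decision", "left")]
right = result.evokeds[("decision", "right")]

# separation tolerance: 3 x the noise level of the difference waveform,
# estimated over the signal-free baseline and pooled across EEG channels
eeg = left.eeg_indices()
base = (left.times >= -500) & (left.times <= -400)
d_base = (left.data - right.data)[np.ix_(eeg, np.flatnonzero(base))]
d_base -= d_base.mean(axis=1, keepdims=True)
tol = 3.0 * float(np.sqrt(np.mean(d_base**2)))

pt = compute_pt(left, right, tol=tol)
sep = max_separation_time(left, right)
print(f"injected divergence onset: {truth.divergence_onset:g} ms before the decision")
print(f"estimated PT: {pt.pt:.0f} ms (crossing at {pt.crossing_time:.0f} ms, "
      f"separation persisted: {pt.persistence_ok})")
print(f"|left - right| is largest {sep:.0f} ms before the decision")
print("a single subject's PT scatters around the injected onset by some tens")
print("of ms (slow background noise moves the last crossing); averaging PT")
print("over a cohort, as the pipeline does, recovers the onset to ~10 ms.")
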