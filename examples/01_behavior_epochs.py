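"""Segment a song timeline into bouts, phrases, and behavioral epochs.

Generates an annotated directed-song session, assembles phrases with the
2-s gap rule, and prints the phrase table and the fraction of the trial
spent in each epoch.
"""

import numpy as np

from periseq import behavior, synth

config = synth.GeneratorConfig()
timeline, truth = synth.gen_timeline(config, seed=1)

print(behavior.phrases_to_frame(timeline.phrases).to_string(index=False))

times = np.arange(0, timeline.trial_end, 1 / config.fps)
mask = timeline.epoch_mask(times)
print("\nepoch occupancy (fraction of frames):")
for label in behavior.EPOCH_LABELS:
    print(f"  {label:10s} {mask.fraction(label):.3f}")

eligible = timeline.eligible_phrases(which="pre")
print(f"\n{len(eligible)}/{len(timeline.phrases)} phrases have 5 s of pre-song silence")
# peri_pre + peri_gap + peri_post together form the peri-song epoch used
# for phrase-index counting; baseline frames are >= 10 s from any vocalization.
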