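"""Respiratory cycles around song: duration, duty cycle, song markers.

Generates an air-sac pressure waveform (quiet ~0.38 s cycles, song
~0.18 s cycles), segments it into inspiration/expiration cycles, aligns
them to song with the inspiration-before-first-intro-note marker, and
summarizes duration and expiratory duty cycle per epoch.
"""

import numpy as np

from periseq import respiration, synth

config = synth.GeneratorConfig()
timeline, truth = synth.gen_timeline(config, seed=6)
pressure = synth.gen_pressure(truth, config, seed=6)
cycles = respiration.segment_cycles(pressure)
print(f"{len(cycles)} respiratory cycles segmented "
      f"(ambient level estimate {pressure.ambient_level:+.4f})")

markers = respiration.song_markers(cycles, timeline, phrase=0)
print("song markers (onset, offset): (%.3f, %.3f) s; planted (%.3f, %.3f) s"
      % (*markers, *truth.pressure_markers[0]))

summary = respiration.summarize_epochs(cycles, markers)
for epoch in ("pre", "song", "post"):
    g = summary[summary.epoch == epoch]
    dur = np.average(g.duration_s, weights=g.n)
    duty = np.average(g.duty_pct, weights=g.n)
    print(f"  {epoch:4s}: duration {dur:.3f} s, duty {duty:.1f} % ({int(g.n.sum())} cycles)")
# Song respiration runs ~2x faster than quiet breathing; duty cycle is
# the percent of each cycle spent in expiration (supra-ambient pressure).
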