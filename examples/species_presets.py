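"""Simulate the two species presets and compare their collective rhythms.

Colonies of both presets synchronise into short-term activity cycles; the
preset with the narrow uniform refractory distribution cycles more slowly
than the one with exponential refractory periods.
"""

from antsync import run_batch

for preset in ("spW", "crassipilis"):
    batch = run_batch(preset, n_replicates=5, base_seed=1, methods=("cwt",))
    periods = batch.dominant_periods[0] / 60.0
    print(f"{preset:12s} dominant periods (min): "
          + ", ".join(f"{p:.1f}" for p in periods)
          + f"  -> mean {periods.mean():.2f} min")

print(
    "\nEach value is one simulated colony's dominant collective period "
    "(Morse-wavelet magnitude peak).\nWith 30+ replicates the means settle "
    "near ~12 min (spW) and ~8 min (crassipilis)."
)
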