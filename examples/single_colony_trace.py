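"""Run one colony, write its activity trace to CSV and summarise its rhythm.

Shows the full pipeline on a single simulation: proportion-active series at
1 s resolution, Gaussian smoothing, min-max rescaling, peak statistics and
the dominant period from both spectral estimators.
"""

from pathlib import Path

from antsync import (
    get_preset,
    run_simulation,
    preprocess,
    detect_peaks,
    ibi_cv,
    lomb_scargle,
    write_trace,
)
from antsync.experiments import decimate_trace
from antsync.wavelet import dominant_period_cwt

params = get_preset("spW").with_seed(42)
trace, events = run_simulation(params)
print(f"simulated {params.n_steps} steps; mean proportion active "
      f"{trace.values.mean():.3f}; {len(events)} logged events")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_trace(out / "colony_trace.csv", decimate_trace(trace, 30))
print(f"wrote 30 s cadence trace to {out / 'colony_trace.csv'}")

pre = preprocess(trace)
cwt = dominant_period_cwt(pre, period_range=(60.0, trace.duration / 4))
ls = lomb_scargle(preprocess(decimate_trace(trace, 30)))
print(f"dominant period: CWT {cwt.dominant_period / 60:.1f} min, "
      f"Lomb-Scargle {ls.dominant_period / 60:.1f} min")

pre30 = preprocess(decimate_trace(trace, 30))
peaks = detect_peaks(pre30, 0.2)
stats = ibi_cv(pre30.times[peaks])
print(f"{len(peaks)} activity peaks; mean inter-burst interval "
      f"{stats.mean_ibi / 60:.1f} min, CV {stats.cv:.2f}")
print("\nA CV well below 1 marks a rhythmic colony; isolated ants are "
      "Poisson-like (CV ~ 1).\nWhen the two estimators disagree (as here), "
      "the colony is expressing both a short cycle and its\nperiod-doubled "
      "partner: the wavelet favours the strong short-cycle episodes, the "
      "periodogram the\nrhythm that dominates the record on average.")
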