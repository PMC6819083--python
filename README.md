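# photoflux

Signal processing and quantification for two-channel fiber photometry,
built for experiments that monitor fluorescent dopamine sensors (e.g.
dLight) in behaving mice, plus the surrounding quantification layers:
behavioral metrics, neuron morphometry, and group statistics.  A
synthetic-data module generates every input the pipeline consumes with
known ground truth, so the whole chain is testable without any recording.

## What it computes

Raw acquisition multiplexes two LEDs on one photodetector by amplitude
modulation (signal channel at 211 Hz, isosbestic reference at 531 Hz).
photoflux recovers each channel by quadrature lock-in demodulation

    env(t) = 2 * sqrt( LP[x·sin(2πf_c t)]² + LP[x·cos(2πf_c t)]² )

with a second-order zero-phase Butterworth low-pass (25 Hz), decimates to
382 Hz, fits the reference to the signal channel by least squares, and
forms

    ΔF/F = (F₄₉₀ − F̂₄₀₅) / F̂₄₀₅,       z = (ΔF/F − median) / MAD

The robust z trace feeds transient detection (prominence ≥ 2 z, FWHM at
half-prominence), peri-event trial features (cue peak, outcome peak,
anti-peak, rebound AUC), and feature–behavior trend statistics.  Companion
modules compute lick bouts (≥ 5 licks/s, 3 s bout gap), learning rates
(OLS slope of cue-period licks across trials), freezing acquisition,
Sholl profiles on SWC morphologies (5 µm concentric shells), soma
morphometry, t tests reconstructed from printed mean ± SEM summaries, the
two-sample KS test, and Bonferroni / Benjamini–Krieger–Yekutieli
two-stage FDR correction.

## Worked example

```python
import numpy as np
import photoflux as pf

# simulate a 10-minute baseline session: 0.5 Hz transients of 6% dF/F,
# shared motion artifact, photobleaching, detector noise
config = pf.SimulationConfig(seed=0)
raw, truth = pf.generate_session(config)

session = pf.demodulate_session(raw)          # lock-in -> 382 Hz
dff, z = pf.process_session(session)          # isosbestic dF/F -> robust z
events = pf.detect_transients(z)              # prominence >= 2 z

n = min(len(dff), truth.true_dff.size)
print(f"recovered dF/F vs truth: r = "
      f"{np.corrcoef(dff.dff[:n], truth.true_dff[:n])[0, 1]:.3f}")
print(f"transient rate: {events.rate_hz:.3f} Hz "
      f"({len(events)} events in {events.analyzed_duration_s:.0f} s)")
print(f"mean height {events.mean_height_z:.2f} z, "
      f"mean FWHM {events.mean_fwhm_s:.3f} s")
```

Output:

    recovered dF/F vs truth: r = 0.994
    transient rate: 0.473 Hz (283 events in 598 s)
    mean height 8.44 z, mean FWHM 0.429 s

The correlation shows the isosbestic division recovering the latent
fractional fluorescence despite bleaching and motion; the detected rate
sits slightly below the generating 0.5 Hz because Poisson events closer
than ~0.2 s merge into single peaks (see `docs/methods.md`).

The same operations are available from the shell:

    photoflux simulate session --seed 0 --out scratch/demo
    photoflux demodulate --raw scratch/demo/raw.csv --out scratch/demo/session.csv
    photoflux process --session scratch/demo/session.csv --out scratch/demo/dff.csv
    photoflux transients --dff scratch/demo/dff.csv --out scratch/demo/events.csv
    photoflux stats adjust --pvalues 0.001,0.01,0.02,0.3,0.9 --method bky_two_stage

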