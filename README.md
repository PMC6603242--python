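# startlekit

A hardware-free acoustic-startle-reflex (ASR) measurement stack for rodent
behavioral audiometry — the software side of a PPI / GPIAS startle setup,
fully testable without animals or hardware.

The acoustic startle reflex — the whole-body twitch evoked by a loud,
sudden noise burst — is inhibited when a perceptible pre-stimulus precedes
the burst. Two paradigms build on this:

* **PPI threshold audiometry** — a faint pure tone precedes the startle
  burst; inhibition at a given level proves the tone was heard, and the
  inhibition-vs-level curve yields a hearing threshold.
* **GPIAS tinnitus screening** — the pre-stimulus is a silent gap in
  ongoing band noise; a tinnitus percept is hypothesized to mask the gap
  and reduce inhibition.

`startlekit` provides every computational stage of such a setup:

| module | what it does |
| --- | --- |
| `stimulus` | tones, band noise, sin²-ramped gaps, startle bursts; 3-channel trial assembly (pre-stimulus, startle, TTL trigger) at 96 kHz |
| `protocol` | seeded, balanced GPIAS / threshold sessions (5 habituation trials, Fisher–Yates order reproducible across animals) |
| `equalizer` | loudspeaker equalization: NLMS system identification, real-cepstrum minimum phase, regularized band-limited inversion (2–20 kHz), TTL latency measurement |
| `response` | ASR amplitude A = max₀≤t≤150ms √((cₓaₓ)²+(c_y a_y)²+(c_z a_z)²) from 3-axis accelerometer traces, 40 Hz zero-phase low-pass, trigger alignment, axis calibration |
| `analysis` | full-combinatorial ratio statistic 1 − median(A_pre/A_base), bootstrap SEs, log-normal MLE, hard-sigmoid threshold fits, rank-sum group comparison |
| `simulate` | virtual animal (log-normal amplitudes, multiplicative inhibition), spring-platform accelerometer model, synthetic colored playback chains — ground truth for every other module |
| `session_io` | organized CSV/JSON session storage, ASCII export, configuration |

The statistics layer also exposes statsmodels-style model objects —
`InhibitionModel(...).fit()`, `HardSigmoidModel(...).fit()`,
`LogNormalModel(...).fit()` — returning results with estimates,
uncertainties, `summary()` tables and plots.

## Worked example

Simulate a GPIAS session for a virtual animal with a known inhibition of
0.5, extract per-trial amplitudes, and estimate the GPIAS statistic:

```python
import startlekit as sk
from startlekit import response, simulate

proto = sk.build_gpias_protocol([8000.0], n_repeats=15, seed=3)
animal = sk.VirtualAnimal(gpias_true=0.5, seed=7)
platform = sk.VirtualPlatform()

recs, truth = sk.simulate_session(proto, animal, platform)
truth["amplitude"] = [
    response.extract_asr(r, platform.calibration()).value for r in recs
]
block = truth[~truth.habituation]          # habituation trials excluded

model = sk.InhibitionModel.from_dataframe(block, "gap", "nogap")
print(model.fit(n_bootstrap=2000, seed=1).summary())
```

```
Inhibition results (gap vs nogap)
=================================
n pre / n base          15 / 15
ratios (full comb.)     225
statistic (1 - median)  0.4667
bootstrap SE            0.0717
bootstrap replicates    2000
95% CI                  [0.3262, 0.6073]
```

The statistic (1 − median of all 225 pairwise gap/no-gap amplitude
ratios) recovers the planted inhibition of 0.5 well within its bootstrap
standard error. The same pipeline with tone trials over a level grid feeds
`HardSigmoidModel`, whose fitted breakpoint is the hearing threshold.

A CLI covers the same flow from a shell:

```sh
startlekit --seed 3 protocol gpias --freq 8000 --repeats 15 --out proto.json
startlekit --seed 3 simulate session --protocol proto.json --out data/
startlekit --seed 3 analyze gpias --table amplitudes.csv --out result.json
startlekit calibrate equalize --excitation x.wav --recording y.wav --out eq.csv
```

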