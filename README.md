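# respcoupling

Analysis of cardiorespiratory coupling at rest from continuous
respiration (RSP) and heart-rate (HR) signals: respiratory sinus
arrhythmia makes HR rise with inspiration and fall with expiration, with
HR trailing respiration by well under a second. `respcoupling`
quantifies that coupling per subject, models it with a pair of nested
linear models, and reproduces it mechanistically with a small simulator.

## What it computes

For each subject's paired 3-minute RSP/HR traces (1 kHz in the original
recordings), after 0.1–1 Hz zero-phase band-pass filtering and
z-scoring:

- **Time-lag and peak correlation** — the integer-sample shift τ
  maximizing the normalized cross-correlation of RSP(t) with HR(t + τ).
  Positive lag means HR is delayed relative to RSP; resting cohorts
  center near +850 ms.
- **Mutual information** — plug-in MI (nats) from the 16×16 joint
  histogram of the two z-scored signals, a nonlinearity-agnostic
  companion to the correlation peak.
- **Two HR models**, fitted by OLS sample-by-sample and compared by the
  corrected Akaike criterion:

  ```
  c-model1:  HRm(t) = b0 + b1·RSP(t)
  c-model2:  HRm(t) = b0 + b1·RSP(t) + b2·dRSP/dt
  ```

  For quasi-sinusoidal respiration, a weighted sum of the signal and its
  derivative is a phase-shifted copy of the signal, so the derivative
  term lets a *linear* model absorb the RSP→HR lag; c-model2 wins AICc
  essentially always, with predominantly negative b2.
- **Cohort summaries** — subjects whose lag is more than 3 scaled MADs
  from the median are flagged as outliers (uncoupled recordings show a
  huge spurious lag and a low correlation peak); lag statistics are
  reported over the remainder.

The package also contains the generative counterpart (`rsa_simulator`):
RSP as an asymmetric smoothed triangular wave, HR as a delayed copy plus
a gain-weighted derivative term,

```
advanced_HR = gain3·(gain1·delayed_RSP + gain2·d(delayed_RSP)/dt) + noise,
```

whose effective RSP→HR lag for a sinusoid is the closed form
`delay − atan2(gain2·ω, gain1)/ω` — turning the gains turns the lag.
A synthetic-cohort generator (`synthetic_cohort`) builds whole study
cohorts from this mechanism (45 subjects, breath rates 0.15–0.30 Hz,
delays ~ N(849, 345²) ms), so the entire pipeline runs and is tested
without any recorded data.

## Worked example

Analyze the default synthetic cohort in memory:

```python
import json
from respcoupling import CohortSpec, RunConfig, analyze_recordings
from respcoupling.pipeline import summaries_to_dict
from respcoupling.synthetic_cohort import iter_recordings

spec = CohortSpec()            # 45 subjects, 180 s at 1 kHz, master_seed 7
recordings = (r for r, _ in iter_recordings(spec))
table, coupling, models = analyze_recordings(recordings, RunConfig())
print(json.dumps(summaries_to_dict(coupling, models), indent=2, sort_keys=True))
```

prints

```json
{
  "coupling": {
    "corr_mi_vs_peak": 0.025488835898023757,
    "corr_mi_vs_peak_p": 0.8679998109963561,
    "lag_mean_ms": 1201.6444444444444,
    "lag_sd_ms": 358.49699856455976,
    "mi_mean": 1.4608957371029747,
    "mi_sd": 0.05509054304264805,
    "n_excluded": 0,
    "n_total": 45
  },
  "models": {
    "n_b1_positive": 19,
    "n_b2_negative": 45,
    "n_cmodel2_wins": 45,
    "n_subjects": 45
  }
}
```

Reading the numbers: every subject is better explained by the
derivative-augmented model (`n_cmodel2_wins: 45`), and every fitted
derivative coefficient is negative (`n_b2_negative: 45`), matching the
injected negative gain2. The mean lag (~1202 ms) exceeds the injected
mean delay (849 ms) because a negative derivative gain *retards* the
effective lag by `atan2(|gain2|·ω, 1)/ω` — the same mechanism, read in
the other direction. MI clusters at a moderate level (~1.46 nats) for
all subjects.

The simulator is also a CLI:

```bash
respcoupling simulate --breath-rate 0.25 --delay-ms 850 --gain2 -0.4 --out demo/
# measured lag 1188 ms (peak corr 0.986); traces in demo/
```

against the sinusoid closed form `850 + atan(0.4·ω)/ω·1000 ≈ 1207 ms`;
the 19 ms difference is the triangular waveform's harmonic content.
Other commands: `respcoupling cohort` (generate a synthetic cohort to
disk), `respcoupling analyze --config run.yaml` (full cohort analysis to
`per_subject.csv` + `summary.json`), `respcoupling summarize` (re-derive
summaries from a per-subject table).

## Layout

| module | role |
| --- | --- |
| `signal_io` | trace/manifest I/O, `SignalTrace` / `SubjectRecording` types |
| `preprocess` | segment extraction, zero-phase band-pass, z-score, derivative |
| `coupling` | lag + peak correlation, histogram MI, outlier rule, summaries |
| `hr_models` | c-model1/c-model2 OLS fits, AICc comparison, tallies |
| `rsa_simulator` | triangular RSP, delay, gain model, sinusoid lag oracle |
| `synthetic_cohort` | seeded cohort generation with ground-truth table |
| `pipeline` | per-subject and cohort orchestration, CSV/JSON outputs |
| `cli` | `respcoupling analyze / cohort / simulate / summarize` |

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
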