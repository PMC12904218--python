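# ciderev

Reverberation is one of the most damaging everyday interferers for
cochlear-implant (CI) listeners: CI processors transmit slow per-channel
amplitude envelopes and discard temporal fine structure, and late
reflections smear exactly those envelopes.  `ciderev` is a simulation and
evaluation toolkit for CI-oriented dereverberation built around
weighted-prediction-error (WPE) filtering with an optional
late-reverberation post-filter (the "WPEPF" variant), together with
everything needed to evaluate such algorithms without access to
proprietary speech corpora or human listeners:

* a shoebox **image-source room simulator** with RT60 and
  direct-to-reverberant-ratio (DRR) metrics,
* an STFT-domain **WPE dereverberator** with a pluggable desired-speech
  PSD (oracle or iterative) and a decay-model **post-filter**,
* a **STOI** implementation (short-time objective intelligibility),
* a **synthetic matrix-sentence generator** (five word-like bursts,
  harmonic carrier with natural jitter, formant shaping, syllabic
  envelope) and the five-fold concatenation / extract-the-fourth
  presentation protocol,
* a **simulated crossover listening study**: psychometric listeners,
  RT60-threshold titration, six test conditions with test/retest, linear
  mixed models on rationalised-arcsine (RAU) scores, Šidák/Bonferroni
  post-hocs, paired subjective ratings and ICC(3,1) reliability.

## The model in brief

Reverberation in the short-time spectral domain is treated as an
autoregressive process per frequency bin: with reverberant observation
$x_{t,f}$, WPE subtracts a delayed linear prediction

$$\hat d_{t,f} = x_{t,f} - \sum_{\tau=\Delta}^{\Delta+L-1} g_{\tau,f}^{*}\, x_{t-\tau,f},$$

where $g$ minimises the prediction-error power weighted by the inverse
desired-speech PSD $\lambda_{t,f}$ (supplied by an oracle from the clean
signal in simulation, standing in for a learned estimator).  The
post-filter then attenuates the residual tail with a Wiener gain whose
late-reverberation PSD follows an exponential decay with constant
$\delta = 3\ln 10 / \mathrm{RT60}$, scaled from the reverberation that WPE
itself removed.

The virtual listening room is 7 m × 6 m × 3.5 m with uniform surface
reflection and a spherical head (16 cm radius) 1.9 m from the source;
reverberation severity is set by inverting the Eyring relation
$\mathrm{RT60} = 0.161 V / (-S \ln(1-\alpha))$, $\alpha = 1-r^2$, then
fine-tuning $r$ until the simulated response's Schroeder T30 matches the
target.

## Worked example

```python
from ciderev import (study_room, simulate_rir, generate_pseudo_sentence,
                     apply_protocol, compute_stoi)
from ciderev.room import rir_metrics

spec = study_room(1.0)            # virtual room tuned to RT60 = 1.0 s
ir = simulate_rir(spec, "left")
m = rir_metrics(ir)
print(f"RT60 = {m.rt60:.3f} s, DRR = {m.drr:.2f} dB")

sentence = generate_pseudo_sentence(seed=0)
for processor in ("none", "wpe", "wpepf"):
    trial = apply_protocol(sentence, ir, processor, rt60=1.0)
    stoi = compute_stoi(sentence.samples, trial.audio, sentence.sample_rate)
    print(f"{trial.condition:>12s}: STOI = {stoi.value:.3f}")
```

prints

```
RT60 = 0.998 s, DRR = -8.68 dB
      reverb: STOI = 0.537
  reverb_wpe: STOI = 0.616
reverb_wpepf: STOI = 0.631
```

i.e. the simulated room achieves its target reverberation time with a
DRR of −8.7 dB at 1.9 m; reverberation drops this sentence's predicted
intelligibility to 0.54, WPE recovers it to 0.62, and the post-filter
adds a further gain — the ordering (reverberated < WPE ≤ WPEPF, with
clean speech untouched) that the whole package is designed to measure.

A complete simulated study (15 listeners, titration, six conditions with
test/retest, mixed-model statistics, ratings, ICC) runs in a few minutes:

```bash
ciderev run-study --n-listeners 15 --seed 1 --outdir results/
```

writing `scores.csv`, `ratings.csv`, `lmm_condition.txt`, `lmm_rt60.txt`,
`icc.txt` and per-outcome rating test tables.  Other CLI entry points:
`ciderev simulate-rir`, `ciderev dereverb`, `ciderev stoi`,
`ciderev stoi-batch`, `ciderev make-stimuli`.

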