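# myodecode

Myoelectric motion decoding for upper-limb interfaces: a complete,
reproducible pipeline comparing **per-channel EMG envelope features**
against **NMF muscle-synergy features**, both classified by an **extreme
learning machine (ELM)**, and evaluated not only offline but in a simulated
real-time loop driving a minimum-jerk virtual arm.

It is aimed at researchers in myoelectric control and motor neuroscience
who want to study the feature-extraction / classifier / online-behavior
stack of an intent decoder without access to human-subject recordings: a
synthetic surface-EMG generator with planted synergy structure stands in
for the experimental sessions, so every stage of the pipeline is testable
end to end.

## The method

**Sessions.** Multi-channel surface EMG (default 7 channels at 1 kHz) is
organized into labeled trials: a training phase with 10 repetitions of each
of 5 motion classes plus rest (3 s trials, 2 s rest between), and a testing
phase with 20 repetitions per motion class in randomized order.

**Preprocessing.** Envelopes are obtained by full-wave rectification
followed by a 4th-order Butterworth low-pass at 10 Hz — zero-phase
(forward–backward) for training data, single-pass causal for the online
simulator.

**EMG features.** A sliding window of 100 samples advanced by 10 samples
(one output every 10 ms) yields, per channel,

- MAV = (1/N) Σₙ |xₙ|
- VAR = (1/(N−1)) Σₙ xₙ²  (uncentered, i.e. a power feature)

so 7 channels give a 14-dimensional feature vector.

**Synergy features.** Training envelopes X (p×q, non-negative) are factored
as X ≈ A·Y with A ≥ 0 the p×k synergy basis and Y ≥ 0 the activation
coefficients, by alternating exact non-negative least squares. The synergy
count k is the smallest value whose cumulative explained variance reaches
90 % with a per-synergy gain below 5 %. At test time coefficients are
obtained in real time by the linear projection Y = A⁺·X (Moore–Penrose
pseudoinverse) and summarized per window by their mean, giving a
k-dimensional feature vector.

**Classifier.** An ELM: a single hidden layer of N random, frozen
triangular-basis neurons h(v) = max(1 − |v|, 0), with output weights solved
in closed form by ridge regression,

    w* = (HᵀH + λI)⁻¹ Hᵀ O,

where O holds one-hot class targets. The hidden-layer size is chosen by
stratified 2-fold cross-validation.

**Online simulation.** Causal envelopes stream through the decoder at 10 ms
steps; a debounced class command drives a virtual arm along minimum-jerk
transitions (10t³ − 15t⁴ + 6t⁵). A trial completes when the arm holds the
commanded pose for 0.5 s. Recorded per trial: movement onset, motion
selection time, motion completion time, and per-sample decoding accuracy;
per class: online accuracy over completed trials, an exponential learning
trend fit y = a·e^(−bx) + c, and across-repetition envelope variability.

## Worked example

```python
from myodecode import ElmSettings, RunConfig, SynthConfig, run_experiment

config = RunConfig(synth=SynthConfig(seed=1),
                   elm=ElmSettings(hidden_grid=(100, 300)))
report = run_experiment(config)
for pathway, entry in report["pathways"].items():
    overall = entry["online"]["overall"]
    print(f"{pathway:8s} dim={entry['feature_dim']:2d} "
          f"n_hidden={entry['n_hidden']} "
          f"offline={entry['offline_accuracy_pct']:.2f}% "
          f"online={overall['online_accuracy_pct']:.2f}% "
          f"completion={overall['completion_time_mean_s']:.2f}s")
print("synergies chosen:", report["pathways"]["synergy"]["chosen_k"])
```

prints

```
emg      dim=14 n_hidden=300 offline=98.86% online=100.00% completion=1.54s
synergy  dim= 4 n_hidden=300 offline=99.38% online=99.95% completion=1.55s
synergies chosen: 4
```

Reading this: the EMG pathway decodes from 14 features (MAV+VAR × 7
channels), the synergy pathway from only 4 — the four planted synergies the
selection rule recovered. Both reach near-perfect offline accuracy on
held-out repetitions and complete every simulated online trial in about
1.5 s (one minimum-jerk transition plus the 0.5 s hold). On these clean
synthetic sessions the two pathways are equally accurate; their difference
shows up in robustness — see `docs/methods.md`.

The same experiment is available from the shell:

```bash
myodecode run-all --config config.yaml --out runs/demo
myodecode synth --out data/            # or stage by stage
myodecode train --session data/training.h5 --features synergy --out models/
myodecode simulate-online --features synergy --model models/elm_synergy.npz \
    --synergy-model models/synergy_model.npz --session data/testing.h5 --out sim/
```

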