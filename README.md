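# sacfield

Neural-field simulation and analysis of saccade reaction times (SRTs) in
the gap task, built around the question of why marmosets launch saccades
faster — yet more variably — than humans.

The package is for oculomotor and computational-neuroscience researchers
who want a desk-scale, fully reproducible version of this modelling
pipeline: a 1-D dynamic neural field standing in for the motor map of
the intermediate superior colliculus, driven by eight component inputs
(visual burst, automated and voluntary motor commands, fixation signals,
nigral-style inhibitory gate, peripheral inhibition) with trial-wise
*controlled variability* — every input parameter drawn from a small
grid of levels — plus the complete SRT-distribution analysis
(anticipatory/express/regular classification, 6-ms histograms, CDFs,
R², MSE, Wasserstein distance, quantile and rank-sum comparisons) and a
calibrated synthetic generator of behavioural data so that every stage
runs without any recordings.

## The model in brief

Field activity `a = σ(βu)` on N = 100 nodes over ±5 mm of collicular
surface (toroidal, Δx = 0.1 mm) evolves in 1-ms steps:

    u(t+Δt) = (1 − Δt/τ) u(t) + (Δt/τ) (c_ext(t) + W a(t)),   τ = 4 ms, β = 0.09

with a lateral-interaction kernel `W = (G − 0.8·max G)·Δx`,
`G_ij = 74.7·exp(−d_ij²/2σ²)`, σ = 0.85 mm — local excitation, global
inhibition. `c_ext` is the signed sum of the eight inputs, each a
Gaussian spatial profile (γ = 0.6 mm, amplitude 1.05) times a
piecewise-linear envelope that rises at RoR % of its MaxVal per ms.
Every node starts at u = −30; a saccade fires when any node outside the
central fixation zone reaches a = 0.7, and SRT = crossing time − target
onset. Marmoset and human configurations differ only in their parameter
grids, organised in cumulative modification steps (marmoset 1–3, human
1–2): step 2 accelerates the visual pathway, step 3 adds occasionally
sluggish disinhibition and voluntary build-up. See `docs/methods.md`
for the full account.

## Worked example

Simulate 2,000 random marmoset trials of the final (step 3) grid and
inspect the distribution:

```
$ sacfield simulate --species marmoset --step 3 --n-trials 2000 --seed 77 --out step3.csv
marmoset-step3: 2000 trials, no-saccade fraction 0.0000
$ sacfield analyze --srt-table step3.csv --species marmoset --out step3_summary.csv
```

or run the whole study as numbered scripts:

```
$ python analysis/01_synthesize_behavior.py
marmoset: n=10000, median=115 ms, min=20 ms, 8.5% beyond 250 ms -> behavior_marmoset.csv
human: n=10000, median=143 ms, min=20 ms, 0.3% beyond 250 ms -> behavior_human.csv
$ python analysis/02_identify_saccade_classes.py
marmoset: boundary 60 ms, 1986 express vs 7124 regular
human: boundary 108 ms, 296 express vs 8850 regular
$ python analysis/03_simulate_model_steps.py
marmoset-step1: median=153 ms, 0.00% beyond 250 ms, no-saccade 0.00% -> model_marmoset_step1.csv
marmoset-step2: median=152 ms, 0.00% beyond 250 ms, no-saccade 0.00% -> model_marmoset_step2.csv
marmoset-step3: median=162 ms, 1.05% beyond 250 ms, no-saccade 0.00% -> model_marmoset_step3.csv
human-step1: median=166 ms, 0.00% beyond 250 ms, no-saccade 0.00% -> model_human_step1.csv
human-step2: median=169 ms, 0.00% beyond 250 ms, no-saccade 0.00% -> model_human_step2.csv
$ python analysis/04_compare_distributions.py
...
species contrast: behavioural p=1.87e-170, simulated p=3.25e-19
```

Reading these numbers: the synthetic behavioural tables carry the
empirical signature (marmosets ~30 ms faster at the median, with ~9% of
visually driven saccades beyond 250 ms against ~0.4% in humans; the
landing-point scan places the anticipatory boundary at 60 ms). On the
model side, the step-2 visual-pathway changes shift the marmoset
distribution left of step 1, the step-3 slow-disinhibition levels create
a >250 ms tail that no step-2 trial reaches, the simulated marmoset
remains faster than the simulated human (rank-sum p ≈ 3e-19), and every
grid cell produces a saccade within the 500 ms window.

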