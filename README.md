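# partiquant

People who inject drugs often prepare slow-release oral morphine tablets
by boiling and cotton-ball filtration; the filtrate can still carry
insoluble particles (coating fragments, crystals, cotton fibres) whose
size distribution determines the vascular risk of injection. `partiquant`
is a Python library for quantifying that particle burden from brightfield
whole-slide scans and for the accompanying morphine-recovery statistics.
It is aimed at harm-reduction and pharmaceutical-analysis researchers who
need a reproducible, testable version of the full analysis chain:

- **synthetic slides** — a seeded generator producing brightfield-like
  rasters with exact ground truth (per-particle footprints, sizes,
  morphologies; bubble and edge-artifact masks), emulating five
  experimental conditions: extraction protocols A–D and a blank
  filtration control;
- **valid-area masking** — intensity thresholding for air bubbles and
  edge disturbances plus a two-class random-forest pixel classifier over
  intensity/texture/morphology features; the valid fluid area is the
  denominator of all densities;
- **dual-learner segmentation with agreement-ranked active learning** —
  two differently configured per-pixel segmenters; unannotated patches
  are prioritised for oracle annotation by the learners' Intersection-
  over-Union (IoU) agreement, IoU(A,B) = |A∩B| / |A∪B|;
- **particle quantification** — 8-connected components, maximum-caliper
  (Feret) sizing, half-open size bins <100 / 100–250 / 250–500 / >500 µm,
  and per-bin densities in particles/mm² of valid fluid;
- **recovery statistics** — dilution-chain back-calculation
  (mg = c_vial · fold · V_flask / 1000), per-protocol replicate summaries,
  recovery efficiency 100·(extracted + remaining)/45 mg label content,
  Welch's unequal-variance t-test (t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂) with
  Welch–Satterthwaite df) and one-way fixed-effects ANOVA per size bin.

The model details, defaults and validation scope are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```bash
python examples/recovery_statistics.py
```

simulates replicate morphine measurements at the per-protocol means/SDs
(n=6 for A and C, n=3 for B and D) and prints the recovery table:

```
| method | n | extracted_mg | sd_extracted_mg | remaining_mg | sd_remaining_mg | sum_mg | efficiency_pct |
|---|---|---|---|---|---|---|---|
| A | 6 | 27.4 | 15.9 | 7.9 | 1.2 | 35.3 | 78.5 |
| B | 3 | 33.1 | 1.3 | 8.3 | 1.3 | 41.5 | 92.1 |
| C | 6 | 34.6 | 9.3 | 7.8 | 0.5 | 42.4 | 94.2 |
| D | 3 | 32.2 | 3.5 | 5.4 | 0.8 | 37.7 | 83.7 |
```

Each row is one extraction protocol: the mean morphine recovered in the
cotton-filtered solution (`extracted_mg`), the mean washed back out of the
cotton ball (`remaining_mg`), their total, and the total as a percentage
of the tablet's 45 mg labelled morphine content. (Values vary with the
simulation seed around the configured means; protocol totals near
40 mg ≈ 90% efficiency, with D lowest, are the expected picture.) The
script also prints the pairwise Welch tests on the totals with
significance stars (*** p<0.001, ** p<0.01, * p<0.05).

Other examples: `examples/simulate_and_quantify.py` (per-bin particle
densities of a synthetic slide against the configured rates),
`examples/active_learning_loop.py` (the agreement-ranked annotation loop
with held-out IoU before/after), `examples/full_experiment.py` (the whole
pipeline end-to-end). A thin CLI mirrors the stages:
`partiquant simulate|mask|quantify|stats|run` (see
`examples/experiment.yaml`).

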