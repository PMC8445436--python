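# vistrain

A headless implementation of the computational core of a virtual-reality
visual-field training device: visual-field modelling on a perimetry grid,
perimeter-to-headset coordinate conversion, the feedback-driven stimulus
relocation procedure that tracks the intact/defect border, a simulated
observer, the blind-spot validation study protocol, and the full
detection-metrics suite (sensitivity/specificity/PPV/NPV, hit rate, marginal
chance-level random hit rate, chance-corrected RATZ index, pooled accuracy,
split-half reliability with the Spearman-Brown correction).

## Layout

| module | role |
| --- | --- |
| `vistrain.geometry` | screen-mm ↔ visual-angle ↔ headset-degree conversions (`2·atan(s/2d)`, 1.54 device scale), built-in `efa`/`svft` device profiles |
| `vistrain.visual_field` | grid field maps (0.75° pitch default), circle/halfplane/quadrant scotomata, anatomical blind-spot model, border-zone extraction, CSV I/O |
| `vistrain.adaptive_trainer` | session scheduling (750 ms display, 2000 ms response window + random break) and the detect-toward / miss-away relocation rule |
| `vistrain.observer_sim` | stochastic observer (fixation jitter, lapses, guesses) and deterministic quota responders for replaying published subjects |
| `vistrain.study_protocol` | 150-trial validation run (25 warm-up / 15 blind-spot + 85 detectable scored / 25 buffer) and cohort aggregation |
| `vistrain.detection_metrics` | confusion-matrix statistics in the study's convention, cohort summaries, reliability, published-table reproduction |
| `vistrain.session_io` | crash-tolerant JSON-lines session logs |

The 40-subject validation table ships as a bundled CSV fixture
(`vistrain/data/validation_cohort.csv`).

## CLI

```sh
vistrain make-field --type blindspot --eye right --pitch 0.75 --extent 20 --out field.csv
vistrain convert --x-mm 100 --y-mm 0 --from efa --to svft
vistrain train --config config.json --field field.csv --observer observer.json \
               --sessions 3 --out-dir runs/
vistrain simulate-study --subjects 40 --seed 7 --out study/
vistrain reproduce-paper --out repro/
```

`reproduce-paper` recomputes every per-subject metric from the bundled
cohort table, writes the per-subject table, the cohort mean/SD summary, the
pooled counts (TN=588, FP=12, FN=28, TP=3372, accuracy 0.990) and a
discrepancy report flagging printed values the formulas do not reproduce
(the RATZ column only).

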