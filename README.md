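# szevents

Cross-subject **seizure event detection** from continuous multi-channel
scalp EEG.

Most automated seizure detectors report how well they classify randomly
sampled 5-second EEG segments. That number says little about clinical
use, where a detector watches one *unseen* patient's continuous,
massively imbalanced recording and must flag seizure *events*. This
package implements the full event-detection pipeline for CHB-MIT-style
recordings (256 Hz, 22-channel bipolar montage, plain-text seizure
annotations) under the three constraints that matter in that setting:

1. **Everything is tested** — all recordings, at their natural
   imbalance (ictal:interictal segments of order 1:300), enter the test
   folds unaltered; only training data is rebalanced by undersampling.
2. **No subject leakage** — folds are subject-disjoint (subject-wise
   5-fold or leave-one-subject-out), so the classifier never sees the
   test patient during training.
3. **Events, not segments** — per-segment predictions are merged into
   events and scored by event sensitivity and false detections per
   hour, the quantities a clinician cares about.

## Pipeline

```
EDF + summary files ──► 5-s segmentation, ictal label if ≥ 60% (3 s) of the
(or synthetic corpus)    window overlaps an annotated seizure
        │
        ▼
92 features × 22 channels per segment (2024 columns): time-domain statistics
and Hjorth parameters; sample-entropy-profile descriptors (SampEn(m=2, r)
swept over r = j·d_max/R); per-band statistics (δ θ α β γ); Welch-spectrum
descriptors (entropies, edge frequencies, moments, band ratios)
        │
        ▼
chi-squared feature selection: per-feature weight w_f = χ²_f / Σχ², averaged
over 5 random subjects × 5 random channels; minimal prefix reaching 0.9
cumulative weight reported, top-34 per channel used (748 columns)
        │
        ▼
random forest on undersampled training folds; n_estimators grid-searched
over {15, 21, 30, 50, 75} on a held-out 30% of training subjects
        │
        ▼
event generation: delete predicted seizure runs ≤ 10 s, then fill ≤ 10 s
gaps between surviving runs
        │
        ▼
event matching: a true event is detected (TP) when pooled detected time
inside it reaches 70% of its duration; fragments of failed events are
discarded (neither TP nor FP); disjoint detections each count one FP
        │
        ▼
Sen = 100·TP/(TP+FN) [%]      FDR = FP / hours observed [/h]
```

A built-in generator (`szevents.simulate`) produces CHB-MIT-like
multi-subject corpora — subject-specific AR(2) backgrounds, rare
seizures carrying an amplitude gain plus a 3–7 Hz rhythmic burst —
so the entire pipeline runs and is tested without any data download.

## Worked example

Post-processing and scoring on a constructed 2-hour timeline:

```python
import numpy as np
from szevents.events import (EventList, PostprocessParams,
                             generate_events, match_events, score_events)
from szevents.segment import LabelSequence

# seven raw predicted seizure runs; two are <= 10 s (deleted) and two
# 10 s gaps are filled, leaving three events
bits = np.array([0,1,1,0,0,0, 1,1,1,0,0,1,1,1, 0,0,0,0, 1,0,0,0,
                 1,1,1,1,0,0,1,1,1,1, 0,0,0,0, 1,1,1,0], dtype=np.int8)
cleaned, events = generate_events(LabelSequence(subject_id="s1", labels=bits))
print("events after post-processing:", len(events))

# five 100-s true events; three covered at 75% by detections, two missed,
# six spurious detections, two hours observed
truth = EventList(np.array([[i*1200.0, i*1200.0 + 100.0] for i in range(5)]))
detected = EventList(np.array([[0,75],[1200,1275],[2410,2485]] +
                              [[6200+150*k, 6230+150*k] for k in range(6)]))
m = match_events(truth, detected, PostprocessParams(coverage=0.70))
s = score_events(m, hours=2.0)
print(f"TP={m.tp} missed={m.missed} FP={m.fp}")
print(f"sensitivity={s.sensitivity_pct:.1f}%  FDR={s.fdr_per_h:.1f}/h")
```

Output:

```
events after post-processing: 3
TP=3 missed=2 FP=6
sensitivity=60.0%  FDR=3.0/h
```

Three of five events detected gives 60% sensitivity; six spurious
events over two hours gives 3 false detections per hour.

End-to-end on a synthetic corpus (8 subjects, two 10-minute records
each, seizure gain 3, leave-one-subject-out; about 5 minutes on one
CPU):

```python
from szevents.simulate import SimConfig, SeizureSignature, simulate_dataset
from szevents.pipeline import run_event_detection

cfg = SimConfig(n_subjects=8, records_per_subject=2, record_duration_s=600,
                seizures_per_subject=(2, 3), seizure_duration_s=(30, 90),
                signature=SeizureSignature(gain=3.0), seed=2024)
ds = simulate_dataset(cfg)
res = run_event_detection(ds.timelines, mode="loo", seed=11, entropy_stride=2)
print(res.scores[res.scores.subject == "overall"])
```

prints an overall row with `sen_pct 95.83`, `fdr_per_h 0.00` (18 of 19
events detected, no false events in 2.67 h). Re-running with
`gain=1.0` — seizures statistically identical to background — collapses
this to `sen_pct 16.67` with `fdr_per_h 15.38`: the detector degrades
to its false-alarm-driven floor, confirming that recovery at gain 3 is
signal, not artifact.

## Command line

```bash
szevents simulate   --out data/ --subjects 8 --records 2 --duration 600 --gain 3 --seed 0
szevents features   --data data/ --out features.parquet --entropy-stride 2
szevents select     --table features.parquet --per-channel-k 34 --out selected.json
szevents train-eval --data data/ --mode loo --out results/
szevents score-events --predictions results/predictions.csv --data data/ --out scores.csv
```

`train-eval` accepts `--mode rs5` (random 80:20 segments, the leaky
baseline), `sw5` (subject-wise 5-fold) and `loo`. Real CHB-MIT data is
consumed from the same layout: one directory per subject containing the
EDF files and `<subject>-summary.txt`, plus a root `manifest.json`
listing the subjects.

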