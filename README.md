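# trnapore

Analysis pipeline for nanopore ionic-current recordings of adapter-ligated
tRNA translocation experiments.

In these experiments a tRNA is ligated into a Y-shaped DNA adapter whose two
strands carry abasic (1'-H deoxyribose) residues flanking the RNA insert. The
molecule is pulled 5'-to-3' through a single alpha-hemolysin pore while a
non-catalytic phi29 DNA polymerase acts as a brake, and the ionic current is
recorded (open channel 68.0–72.5 pA, 100 kHz digitisation, 5 kHz analog
Bessel filter). The two abasic residues produce distinctive high-current
marker states (33.5–36.5 pA) that bracket the RNA-dependent portion of the
signal, so a complete end-to-end translocation shows a leading marker, an
intervening region containing a low-current RNA state (<26.5 pA), and a
trailing marker at the end of the blockade.

`trnapore` implements, as a tested library plus CLI:

* **synthetic squiggle generation** with planted ground truth — open-channel
  baseline, piecewise-constant blockade states, Gaussian noise, and a causal
  Bessel stage emulating the analog filter; dwell times follow log-normal
  populations parameterised in log10 seconds;
* **trace I/O** (columnar text and HDF5) and tab-separated event, segment and
  feature tables;
* **digital Bessel filtering** (default 2 kHz, 4 poles; causal or zero-phase);
* **blockade-event detection**: events open below a 45/55 pA entry cutoff
  after the open channel is established, close at the last upward cutoff
  crossing before open-channel re-entry, and must exceed 0.1 ms; long-event
  selection keeps self-terminating blockades >1 s;
* **band segmentation** of each event into marker-high / low / mid segments
  (markers ≥2 ms in 33.5–36.5 pA; low ≥10 ms below 26.5 pA);
* **marker-rule classification** of long events into
  `LEADING_AND_TRAILING` / `LEADING_ONLY` / `TRAILING_ONLY` / `OTHER`
  and selection of complete translocations (exactly two markers);
* **region I–III feature extraction**: region I runs from event start through
  the leading marker, region II is the inter-marker RNA-dependent span,
  region III runs from the trailing marker to event end;
* **tRNA discrimination**: per region, events are represented by
  (log10 duration, mean pA); a soft-margin linear SVM (C-SVC, linear kernel,
  C = 10) is assessed by fivefold cross-validation repeated 50 times,
  reporting the mean and SD of 250 **balanced accuracy** scores

  BA = ( pred(+1)/true(+1) + pred(−1)/true(−1) ) / 2,

  plus population dwell statistics (log10 mean ± SEM, two-tailed Welch
  t-test).

## Worked example

Generate the default calibrated two-class cohort (80 events per class; the
adapter-dependent regions I and III share one distribution across classes,
region II differs between classes) and cross-validate each region:

```python
from trnapore.synthetic_squiggle import make_two_class_cohort
from trnapore.discrimination import crossvalidate, features_from_cohort

cohort = make_two_class_cohort(n_per_class=80, seed=1)
for region in ("I", "II", "III"):
    X, y = features_from_cohort(cohort, region)
    report = crossvalidate(X, y, folds=5, repeats=50, C=10.0, seed=1)
    print(f"region {region:>3}: balanced accuracy "
          f"{100*report.mean:.1f} +/- {100*report.sd:.1f}% "
          f"({report.scores.size} scores)")
```

which prints

```
region   I: balanced accuracy 52.1 +/- 5.5% (250 scores)
region  II: balanced accuracy 87.3 +/- 5.3% (250 scores)
region III: balanced accuracy 50.7 +/- 6.6% (250 scores)
```

Only the RNA-dependent region II separates the two classes; the shared
marker regions I/III sit at chance, confirming that the discriminating
signal comes from the tRNA itself.

The full trace-level pipeline runs from one YAML config:

```sh
trnapore run --config config.yaml --out-dir artifacts --seed 1
```

writing the trace, ground-truth manifest, event/segment/feature tables,
category table, accuracy report and a provenance record.

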