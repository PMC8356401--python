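# strokestop

A tested implementation of the **Stroke-Stop** risk index for patients with
atherosclerotic internal carotid artery (ICA) stenosis, together with the
cohort-level analysis around it and a calibrated synthetic-cohort simulator.

## Who this is for

Vascular-medicine researchers and biostatisticians who want to compute,
audit, or stress-test the Stroke-Stop points scale — a proposed screening
index that combines three stroke risk factors measurable in an outpatient
duplex/ELISA workup:

* the **SDVR**, the ratio of peak systolic to end diastolic blood-flow
  velocity within the ICA (PSV/EDV, dimensionless) — a proxy for stenosis
  severity,
* the plasma concentration of **Lp-PLA2** (lipoprotein-associated
  phospholipase A2, µg/l) — an inflammatory vascular biomarker, and
* the ultrasound **plaque echogenicity** class, encoded as a density
  coefficient SF.

## The index

```
index = (SDVR × Lp-PLA2) / SF,   SF = 5 (echolucent), 10 (heterogeneous), 15 (echogenic)
```

The numerator SDVR × Lp-PLA2 is the area of the rectangle the two
measurements span in the (SDVR, Lp-PLA2) plane; SF rescales it per plaque
class so that 100 points marks the high-risk boundary. Bands:

| index | band |
|---|---|
| < 70 | low |
| 70 – 100 | medium |
| > 100 | high |

Echolucent and heterogeneous plaques are the "unstable" classes, echogenic
plaque is "stable"; at the same measurements an echolucent plaque scores
2× a heterogeneous and 3× an echogenic one. The index is a points scale,
not a calibrated probability — no outcome model is attached.

## Worked example

```python
>>> import strokestop as ss
>>> ss.stroke_stop_index(sdvr=3.0, lp_pla2=285.0, plaque="heterogeneous")
85.5
>>> ss.risk_band(85.5)
'medium'
```

A patient with SDVR 3.0, Lp-PLA2 285 µg/l and a heterogeneous plaque scores
3.0 × 285 / 10 = **85.5 points → medium risk**; with an echolucent plaque
the same measurements give 171 points → high risk.

The scorer is also available as a scikit-learn estimator over patient
DataFrames:

```python
>>> import pandas as pd
>>> from strokestop import StrokeStopScorer
>>> X = pd.DataFrame({"sdvr": [3.0, 2.3], "lp_pla2": [285.0, 285.0],
...                   "plaque": ["heterogeneous", "echolucent"]})
>>> est = StrokeStopScorer().fit(X)
>>> est.score_samples(X)
array([ 85.5, 131.1])
>>> est.predict(X)
array(['medium', 'high'], dtype=object)
```

From a shell:

```
$ strokestop score --sdvr 3.0 --lp 285 --plaque heterogeneous
sdvr: 3.0000
sf: 10
index: 85.5000
band: medium
```

The package bundles the 70-patient study cohort table (published index,
Lp-PLA2, plaque class and stenosis percent per patient):

```
$ strokestop cohort
n_total: 70
n_by_band: {"low": 6, "medium": 16, "high": 48}
lp_pla2_min: 252.7
lp_pla2_max: 328.6
```

i.e. 6 patients in the low band, 16 medium, 48 high, with cohort Lp-PLA2
spanning 252.7–328.6 µg/l. `strokestop simulate` writes seeded synthetic
cohorts with the study's group structure, and `strokestop riskmap` prints or
plots the banded partition of the (SDVR, Lp-PLA2) plane per plaque class.

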