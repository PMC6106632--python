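# kidscore

Morphokinetic embryo evaluation for IVF: a tested reimplementation of the
**KIDScore D3 Basic** avoidance classifier together with the statistics used
to validate it clinically against standard morphology, and a seeded synthetic
cohort generator so the entire pipeline runs without any patient data.

## Who this is for

Clinical embryologists and reproductive-medicine statisticians who want a
transparent, scriptable version of the time-lapse ranking algorithm that ships
inside EmbryoScope incubators — to audit it, run sensitivity analyses on its
thresholds, or reproduce the arithmetic of its published external validation
(768 single-embryo transfers, day-3 and blastocyst stage, with pregnancy,
clinical pregnancy and live birth as nested endpoints).

## The model

Each embryo is annotated from time-lapse images with event times in hours post
insemination (HPI): tPNf (pronuclear fading), t2, t3, t5, t8 (first frames
with 2, 3, 5, 8 cells), and so on. The classifier applies five exclusion
splits strictly in order and stops at the first that fires:

| split | criterion | class |
|---|---|---|
| 1 | too fast start: t3 − tPNf < 11.48 h | KID1 |
| 2 | too slow start: t3 ≥ 42.91 h | KID2 |
| 3 | irregularity index (t5−t3)/(t5−t2) < 0.3408 | KID3 |
| 4 | irregularity index ≥ 0.5781 | KID4 |
| 5 | 8-cell stage not reached before 66 HPI | KID4 |
| — | passed everything | KID5 |

The irregularity index is the fraction of the 2-cell → 5-cell interval spent
after the 3-cell stage; extreme values flag uneven division pacing. KID4
therefore contains two embryo types, and results carry the rule that fired.
Being an *avoidance* model it deselects embryos with adverse features rather
than selecting a narrow ideal window, which keeps many embryos in the top
class.

Alongside the classifier the package implements Gardner blastocyst grade
parsing (`4AB` → expansion 4, ICM A, TE B) and day-3 cleavage grading, their
grouping into TQE/GQE/PQE/Slow quality classes, the "clinically usable"
(3BB-or-better) rule, and per-class PR/CPR/LBR rates, contribution shares,
fold changes, Fisher's exact test and ordinal trend fits.

## Worked example

```bash
kidscore simulate --seed 1 --out cohort.csv
kidscore score cohort.csv --out scored.csv
kidscore summarize scored.csv --by kid --endpoint lbr --out table.csv
```

`simulate` draws a synthetic cohort of 768 transfers (116 day-3 fresh,
287 day-5 fresh, 285 day-5 frozen, 80 day-6 frozen) with the study's class
distribution and class-conditional outcome probabilities; `score` appends
`kid_class`, `kid_rule` and `kid_index` columns; `summarize` tabulates
per-class rates and contributions. The table printed for seed 1:

```
class,n,c_transfers,pr,c_pr,cpr,c_cpr,lbr,c_lbr
KID1,33,4.3,18.2,1.5,15.2,1.7,15.2,1.8
KID2,56,7.3,42.9,6.2,28.6,5.4,26.8,5.3
KID3,44,5.7,34.1,3.9,27.3,4.1,22.7,3.6
KID4,169,22.0,51.5,22.4,34.9,19.9,32.5,19.6
KID5,466,60.7,55.2,66.1,43.8,68.9,42.1,69.8
```

Reading the KID5 row: 466 of 768 transfers (60.7%) ranked in the top class,
their live birth rate was 42.1%, and they account for 69.8% of all live
births in the cohort — the signature of an avoidance model: the top class is
large and carries most of the successful outcomes. `kidscore validate`
recomputes the published summary-table arithmetic from the packaged digest
and reports pass/fail per quantity (including one known misprint in the
per-group pregnancy counts, reported as informational).

## Layout

- `kidscore.cohort` — embryo/annotation data model, cohort CSV I/O, validation
- `kidscore.model` — thresholds, irregularity index, the five-split classifier
- `kidscore.morphology` — Gardner and cleavage grade parsing and classing
- `kidscore.outcomes` — rates, contributions, Fisher test, trend, cross tables
- `kidscore.digest` — the published summary tables as checked fixture data
- `kidscore.synthetic` — constructive-inverse cohort generator
- `kidscore.cli` — `kidscore simulate|score|morph|summarize|validate|pipeline`

See `docs/methods.md` for the modelling assumptions, numerical conventions
and known limitations.
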