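# potencyscreen

Ligand-based virtual screening for binary bioactivity classification —
built for the setting where thousands of molecules have been screened
against a cell-line panel (e.g. the NCI-60 growth-inhibition screen) and
the task is to triage new structures into likely **active** (e.g.
anticancer) and **inactive** classes from their fingerprints alone,
irrespective of target or mechanism.

The package combines three classifiers over named binary fingerprint bits
and reports them under a repeated, stratified cross-validation protocol:

1. **MCC-based fingerprint selection.** For each fingerprint *i*, the
   class-wise bit means are

   F<sub>i</sub><sup>A</sup> = Σ<sub>j</sub> D<sub>i</sub><sup>j</sup> / N<sub>A</sub>,  F<sub>i</sub><sup>I</sup> = Σ<sub>j</sub> D<sub>i</sub><sup>j</sup> / N<sub>I</sub>

   where D<sub>i</sub><sup>j</sup> ∈ {0,1}. A molecule's compound score is
   C<sub>score</sub> = F<sup>A</sup> − F<sup>I</sup> if the bit is set and
   F<sup>I</sup> − F<sup>A</sup> otherwise; sweeping the decision threshold
   over all distinct C<sub>score</sub> values gives each fingerprint a
   standalone Matthews correlation coefficient (MCC). Fingerprints with
   MCC > 0.2 (strict) are kept.

2. **Potency score.** Two Tanimoto coefficients are computed between a
   query X and each reference Y: T<sub>s1</sub> = |X∧Y| / |X∨Y| over set
   bits, and T<sub>s0</sub>, the same coefficient on the complemented
   vectors (shared *absences*). With H<sup>a</sup>/H<sup>n</sup> the
   highest similarity to any active / inactive reference,

   P<sub>s</sub> = max(H<sup>a</sup>T<sub>s1</sub>, H<sup>a</sup>T<sub>s0</sub>) − max(H<sup>n</sup>T<sub>s1</sub>, H<sup>n</sup>T<sub>s0</sub>) ∈ [−1, 1],

   and a query is called active when P<sub>s</sub> exceeds a threshold
   (default 0). Unlike a plain nearest-neighbour Tanimoto search, the score
   is penalized by proximity to known inactives.

3. **RBF-SVM and hybrid.** A support vector machine with an RBF kernel
   (γ = 0.1, C = 6, class-cost ratio j = 1) is trained on the selected
   bits. Because the SVM decision value and P<sub>s</sub> live on different
   scales, each is min–max normalized to [−1, 1] on the training set, and
   the **hybrid score is their arithmetic mean** — similarity evidence when
   a close reference exists, margin evidence when none does.

Evaluation is stratified 5-fold cross-validation repeated (default 20
times), with the fingerprint list, reference set, SVM and score
calibrations all refit inside each training fold; sensitivity, specificity,
accuracy, MCC, FPR and rank-based AUC are averaged over repeats on a fixed
threshold grid. A functional-group profiler (per-class frequency F_G and
mean count M_G over an editable SMARTS vocabulary) supports the companion
substructure analysis.

## Worked example

```python
from potencyscreen import (SimConfig, generate_dataset, all_fingerprint_stats,
                           select_fingerprints, cross_validate, CVConfig)

# synthetic benchmark: 400 molecules, 40 bits of which 6 are informative
cfg = SimConfig(n_active=200, n_inactive=200, n_fingerprints=40,
                n_informative=6, seed=42)
ds, planted = generate_dataset(cfg)

stats = all_fingerprint_stats(ds)
selected = select_fingerprints(stats, mcc_cutoff=0.2)
print(f"selected {len(selected)} fingerprints: {selected[:4]} ...")

for method in ("potency", "margin", "hybrid"):
    res = cross_validate(ds, method, CVConfig(folds=5, repeats=5, seed=7))
    m = res.at(0.0)
    print(f"{method:7s}  accuracy {m.accuracy:6.2f} %  MCC {m.mcc:.3f}  "
          f"AUC {res.auc_mean:.3f}")
```

prints

```
selected 6 fingerprints: ['FP4_info', 'FP6_info', 'FP1_info', 'FP3_info'] ...
potency  accuracy  99.30 %  MCC 0.986  AUC 0.999
margin   accuracy  99.65 %  MCC 0.993  AUC 1.000
hybrid   accuracy  99.60 %  MCC 0.992  AUC 1.000
```

Selection recovered exactly the six planted informative bits; all three
classifiers then separate the classes almost perfectly on this easy
synthetic set (accuracy is the percent of held-out molecules classified
correctly at threshold 0, averaged over 5 × 5 cross-validation folds).

The same pipeline is available from the shell:

```sh
potencyscreen simulate --seed 42 --out bench.csv
potencyscreen select   --table bench.csv --mcc-cutoff 0.2 --out stats.csv
potencyscreen evaluate --table bench.csv --method hybrid --repeats 5 \
                       --seed 7 --out report/
```

plus `fingerprint` (MACCS / SMARTS-key matrices from SMILES), `score`
(potency-score a query table, reporting the four nearest-reference
similarities and the nearest active/inactive ids), `train` / `hybrid`
(persist and apply an SVM + calibration), and `groups` (functional-group
profiles).

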