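# ramanstage

Single-cell Raman spectroscopy pipeline for **staging proliferating human
hepatocytes**.  Primary human hepatocytes (PHH) can be expanded in vitro
into proliferating hepatocytes (ProliHHs) for liver cell therapy, but they
dedifferentiate toward a progenitor-like state with passaging — and
transplantation-grade quality control needs a fast, label-free way to tell
passage stages apart.  Raman microspectroscopy reads out a cell's
biochemical composition (proteins, lipids, glycogen, aromatic amino acids)
from a single ~10 s acquisition; this package turns raw single-cell spectra
into stage calls and band-level biochemistry.

It is aimed at spectroscopists and cell-therapy QC developers, and covers:

* **Preprocessing** — cosmic-ray despiking (robust first-difference
  z-score), fluorescence baseline removal (asymmetric least squares on a
  Whittaker smoother: min Σwᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)², wᵢ = p above / 1−p below
  the fit), and total-area normalization.
* **Band quantification** — trapezoidal integration of the 13 reported
  fingerprint bands (480 … 1744 cm⁻¹) with group medians and pooled
  Student's t comparisons (ns/*/**/***/**** annotation).
* **Chemometrics** — PCA and Fisher LDA (fitted in a 99 %-variance PCA
  subspace, directions mapped back to channel space), with top-loading
  wavenumber extraction.
* **Stacked classification** — six tuned base learners (KNN, PCA-LDA,
  PLS-DA, linear SVM, RBF SVM, random forest) whose out-of-fold class
  probabilities feed a gradient-boosting meta-learner; evaluation as a
  prediction-by-reference confusion matrix with per-class sensitivity,
  specificity and overall accuracy.
* **Synthetic data** — a generator that emulates the three-stage class
  structure (PHH, P1, P4; Gaussian bands + fluorescence background + noise
  + cosmic spikes) with full ground truth, so the whole pipeline is
  testable without any instrument data.

See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

```python
import numpy as np
from ramanstage import bands, classify, preprocess, synthetic

# 1. generate a labelled synthetic study: 3 stages x 100 cells
cfg = synthetic.SyntheticConfig(n_per_class=100, seed=7)
dataset, truth = synthetic.generate_dataset(cfg)

# 2. clean every spectrum: despike -> baseline -> area-normalize
clean = preprocess.preprocess_set(dataset)

# 3. band semi-quantification: PHH vs passage 4
table = bands.band_table(clean)
stats = bands.compare_groups(table, "PHH", "P4")
print(stats[["band", "median_a", "median_b", "t", "star"]].head(4).to_string(index=False))

# 4. stacked two-layer classifier on a 75/25 split
train, test = classify.split_train_test(clean, classify.SplitSpec(seed=7))
bundle = classify.train_stacked(train, cv=classify.CVSpec(folds=5, repeats=2, seed=7), seed=7)
report = classify.evaluate(bundle, test)
print(report.confusion)
print("overall accuracy:", report.overall_accuracy, "%")
```

Output:

```
   band  median_a  median_b          t star
    480  0.034381  0.027058  12.756765 ****
    831  0.036263  0.027608  15.075812 ****
840-860  0.044579  0.027604  26.210504 ****
   1003  0.045241  0.079338 -35.380952 ****
reference  P1  P4  PHH
predicted             
P1         25   0    0
P4          0  25    0
PHH         0   0   25
overall accuracy: 100.0 %
```

Band areas are fractions of each spectrum's total scattering (the spectra
are area-normalized), medians per group; positive *t* means the first group
is higher.  Glycogen (480), tyrosine (831) and polysaccharide (840–860)
fall from PHH to P4 while phenylalanine (1003) rises — the biochemical
signature of dedifferentiation the classifier exploits.  At this noise
level (5 %) the three stages separate perfectly; the stacked model's value
shows at higher noise, where it matches or beats the best single learner.

The same run is available from the shell:

```bash
ramanstage simulate --out data --n-per-class 100 --seed 7
ramanstage preprocess --in data/spectra.csv --meta data/meta.csv --out clean.csv --qc qc.csv
ramanstage bands --in clean.csv --meta data/meta.csv --out bands.csv --stats stats.csv
ramanstage run --config pipeline.yaml --out runs/demo      # full pipeline from YAML
ramanstage reference-report                                 # frozen published counts
```

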