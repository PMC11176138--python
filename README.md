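# relaxrepro

Quantitative T2/T2* relaxometry of iron-oxide-enhanced tumor MRI, with a
full in-silico test-retest study: synthetic multi-echo acquisitions,
voxel-wise decay fitting, a muscle-referenced tumor measurement, and
repeatability/reproducibility statistics.

## The problem

Iron oxide nanoparticles (IONPs) are phagocytosed by tumor-associated
macrophages and shorten the transverse relaxation times T2 and T2\* where
they accumulate, so a *drop* in a tumor's mean T2/T2\* after contrast is an
imaging biomarker of macrophage content. Using that drop quantitatively
requires knowing how repeatable the measurement is: how much the mean T
varies between duplicate acquisitions (repeatability) and between readers
delineating the tumor (reproducibility).

`relaxrepro` implements that measurement chain for researchers working
with multi-echo mouse-tumor MRI, and — because such image data are rarely
deposited — ships a first-class simulator that emulates the study design:
a leg-cross-section digital phantom with tumor and contralateral muscle,
the four echo-train protocols used at 3 T and 7 T, Rician acquisition
noise, rate-additive IONP contrast, and perturbed reader delineations.

## The model and statistics

Every voxel's magnitude signal across the echo train is fit with a
mono-exponential decay with constant offset,

    S(t) = A + S0 · exp(−t / T),

where *A* ≥ 0 is an absolute bias, *S0* ≥ 0 the initial signal, and
*T* ∈ [0.1, 1000] ms is T2 or T2\*. The bounded least-squares problem is
solved by variable projection (exact non-negative linear solve for
*A*, *S0* at fixed *T*; log-grid scan plus golden-section refinement of
the 1-D profile in *T*), vectorized over whole volumes.

The tumor measurement follows a standardized three-step procedure:
outline the tumor, exclude pixels whose minimum-TE signal falls below a
fixed fraction of the mean contralateral-muscle signal (7% at 7 T, 30% at
3 T), and record the mean T of the retained volume.

Agreement between paired measurements x, y is summarized by

* **Lin's CCC** = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with a 95% CI from
  the Fisher z-transform and Lin's asymptotic variance;
* **Bland–Altman**: mean difference ± 1.96·SD of differences (95% LOA);
* **CoV (%)**: per-subject |x−y|/√2 divided by the pair mean, averaged,
  classified as excellent (≤5%), good (≤10%), moderate (≤20%) or poor.

## Worked example

`examples/simulate_and_map.py` simulates one subject at 7 T, applies
contrast calibrated to shorten the tumor mean from 14.2 to ≈10.2 ms, fits
the map and measures the tumor:

```
pre -contrast tumor mean T2*: 14.19 ms  (591/591 voxels retained)
post-contrast tumor mean T2*: 10.40 ms  (591/591 voxels retained)
```

The ~3.8 ms drop is the contrast effect the biomarker reports; the
retained-voxel counts show the muscle-referenced mask kept the whole
tumor at this SNR. `examples/agreement_statistics.py` prints the
agreement statistics for a toy test-retest set:

```
CCC: 0.977 (95% CI 0.930-0.992)   1 = perfect agreement
Bland-Altman: mean diff -0.38 ms, 95% LOA [-2.40, +1.64] ms
CoV: 2.33%  ->  excellent (<=5% excellent, <=10% good, <=20% moderate, >20% poor)
```

The other examples fit a single noisy voxel (`fit_decay_curve.py`) and run
a scaled-down end-to-end study (`run_small_study.py`).

## Command line

A thin CLI mirrors the pipeline stages and interoperates through NIfTI +
JSON sidecar and CSV files:

```bash
relaxrepro simulate --field 7 --weighting t2star --snr 50 --seed 3 --subjects 2 --out sim/
relaxrepro fit --in sim/S01_pre_acq1.nii.gz --out sim/S01_map.nii.gz
relaxrepro measure --series sim/S01_pre_acq1.nii.gz --map sim/S01_map.nii.gz \
    --roi sim/S01_roi.nii.gz --out measurements.csv
relaxrepro agree --measurements measurements.csv --out report/
relaxrepro run --seed 0 --out study_out/   # the full 15-subject study
```

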