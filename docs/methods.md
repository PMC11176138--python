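# Methods

## Signal model and voxel-wise fitting

Magnitude signal in a multi-echo acquisition is modelled per voxel as
`S(t) = A + S0·exp(−t/T)` with an absolute bias `A ≥ 0` (the noise
floor/baseline a magnitude image carries), initial intensity `S0 ≥ 0`, and
relaxation time `T` (T2 for spin-echo trains, T2\* for gradient-echo) in
milliseconds. The offset is a free parameter, not fixed: disabling it
(`FitOptions(fit_offset=False)`) reduces to the two-parameter model.

Fitting minimizes the residual sum of squares over `(A, S0, T)` subject to
`A, S0 ≥ 0` and `T ∈ [0.1, 1000] ms` — bounds that cover the observed
tumor/muscle range (≈10–65 ms) with wide margin. The solver uses variable
projection: at fixed `T` the model is linear in `(A, S0)`, and the
non-negative 2-variable linear subproblem has an exact closed-form answer
(interior 2×2 solution, or the better of the `A=0` / `S0=0` edges). The
resulting 1-D profile objective in `T` is scanned on a 64-point log-spaced
grid and the bracketing interval refined by golden-section search to a
relative tolerance of 1e-10 (well inside the 200-iteration cap). Each
voxel's signal is first normalized to unit peak, which makes the fit
structurally scale-equivariant (`A`, `S0` scale with the data, `T` is
scale-free) and keeps the profile arithmetic well conditioned.

This profile solver is exact for noiseless data and by construction never
worse than a grid search; the test suite verifies both against a
brute-force `(A, S0, T)` grid oracle and an independent per-voxel bounded
Levenberg–Marquardt fit. Degenerate voxels — non-finite signal, no decay
(`S0 → 0`), or `T` pinned at a bound — are flagged unconverged and
propagate as NaN, never as zeros, so they cannot bias ROI means downward.

A log-linear seed (`loglinear_init`) is provided for users who want a fast
closed-form estimate: it tries two offset candidates (0 and the minimum of
the last echo quartile), fits a line to `log(signal − Â)` over samples
above 15% of the peak residual, and keeps the candidate with the lower
full-model RSS. It is exact for offset-free noiseless decays and within
~12% when a substantial offset is present; the profile solver does not
depend on it.

At SNR 50 the median relative error of fitted `T` in tumor tissue is
≈5–6% on the 7 T gradient-echo train. This is intrinsic estimator
variance of the three-parameter model at that noise level — an
independent bounded nonlinear least-squares oracle lands on the same
voxel-wise estimates to six decimals — and averages out over an ROI.

## Phantom and acquisition simulator

The phantom is a two-leg cross-section on a 64×64×3 grid (configurable):
one leg carries the tumor (a disc that may extend past the leg outline,
mimicking intra- plus extraosseous growth) and a small bone core; the
contralateral leg supplies the reference calf-muscle ROI. Per-voxel decay
parameters are drawn from lower-truncated normals (`T > 0.1 ms`,
`S0, A ≥ 0`). Default arbitrary-unit intensities are S0 = 100 (tumor),
80 (muscle), 15 (bone) with the offset `A` at 5% of tissue S0.

Echo trains, matrices and slice thicknesses for the four protocols
(3 T/7 T × T2\*/T2) are the published acquisition parameters expanded as
minimum TE + k·spacing; the simulator keeps the echo timing but uses the
phantom grid as its matrix.

Noise is Rician — the physically standard model for magnitude MRI: the
noiseless signal is perturbed by independent Gaussian noise of standard
deviation σ in two quadrature channels and the magnitude taken, so
background converges to the Rayleigh mean σ√(π/2) and low-SNR voxels are
biased upward. SNR is defined as mean tumor S0 over per-channel σ
(default 50; the in-vivo tumor SNR is not reported, so this is a declared
operating point, not an inference). A pure-Gaussian option exists for
analytic tests; `snr=None` disables noise.

Contrast is modelled as rate addition: IONP uptake adds a non-negative
per-voxel rate, `1/T_post = 1/T_pre + ΔR`, with `ΔR` gamma-distributed
(shape 4, i.e. 50% coefficient of variation) to emulate heterogeneous
nanoparticle uptake; muscle and bone receive 10% of the tumor mean
increment (systemic circulation). The population mean increment is
calibrated in rate space so the tumor mean moves from the pre-contrast to
the post-contrast group mean. Monotonicity is structural: rates are only
ever added, so post-contrast T is voxel-wise ≤ pre-contrast T.

Simulated readers perturb the reference tumor delineation slice-by-slice
(readers draw 2-D ROIs): per pass, inner- and outer-boundary voxels are
flipped with probability 0.25. The muscle ROI is shared between readers
(single reference definition in the standardized procedure). Perturbed
masks empty of voxels, or falling below a Dice floor (default 0.7)
against the reference, raise rather than silently degrade.

## Study design and its defaults

The default study is 15 subjects × {3 T, 7 T} × {T2\*, T2} × {pre, post}
× 2 acquisitions × 2 readers = 480 measurements. Duplicate acquisitions
are the same phantom with independent noise realizations (no motion or
drift model); readers re-delineate independently for every series, so
repeatability includes intra-reader delineation variance, not just noise.

Tumor relaxation times use a two-level hierarchy: each subject draws a
tumor mean from a normal with the published group mean and SD for its
(field, weighting, state) cell — e.g. 14.2 ± 2.35 ms for 7 T T2\*
pre-contrast — and voxels scatter around the subject mean with a 15%
coefficient of variation. The between-subject level is essential: CCC
measures how well the method separates subjects, and a cohort of
identical tumors would make agreement undefined. Muscle values
(T2\* 22/14 ms, T2 32/25 ms at 3 T/7 T) and bone are plausible operating
points chosen once; they are not reported quantities. Subject-level
contrast uptake is scaled by a truncated normal factor (CV 0.3), widening
the post-contrast between-subject spread as observed in vivo.

Seeding: every random draw derives from `SeedSequence(base_seed, key…)`
where the key encodes subject, field, weighting, state, acquisition,
stage and reader, so adding subjects or strata never reshuffles existing
draws and the whole pipeline is bit-reproducible from one integer.

## Measurement and agreement analysis

The muscle reference is a single mean over the 3-D muscle ROI of the
minimum-TE image of the mapping sequence itself (the mask operates on the
map's own voxel grid). Exclusion is strict — a pixel strictly below
`fraction × reference` is dropped, ties retained — and applied per volume
by default (`per_slice=True` is available; the original software's
behaviour at this level is not documented). Mean T pools retained, validly
fitted voxels across all slices, unweighted.

Comparisons are built per parameter (T2\*, T2), pooling measurements over
field strength and contrast state by default so each pairing unit is a
(subject, field, state) cell — the granularity of a per-parameter summary
table; a design config exposes stratified alternatives, and strata are
never pooled implicitly. Repeatability pairs a reader's acquisition 1 vs
2; reproducibility pairs the two readers within an acquisition. CCC uses
1/n moment estimators with a Fisher-z CI (Lin's 1989 asymptotic variance);
Bland–Altman uses exactly 1.96 (not a t quantile) with the n−1 SD. The
CoV reading of "SD of the means over the average of means" is taken
per subject — two-point SD `|x−y|/√2` over the pair mean, averaged across
subjects — since the alternative (SD of subject means over the grand
mean) measures between-subject spread, not test-retest precision; an RMS
aggregation is available behind `cov_agg="rms"`. A Shapiro–Wilk p-value
on the paired differences is recorded per comparison as descriptive
output only, as is a linear regression of pre-contrast mean T on field
strength in the manifest.

## What the simulation does and does not show

Passing tests demonstrate that the pipeline is self-consistent: known
decay parameters are recovered, the measurement procedure reproduces
phantom truth, contrast-induced shortening and the 3 T > 7 T ordering
propagate end to end, and agreement statistics respond correctly to
noise. The simulator omits B0/B1 inhomogeneity, susceptibility structure
beyond a scalar T2\*, motion, partial-volume mixing and scanner-specific
reconstruction, and its readers differ only in boundary jitter — so
simulated CoVs (≲1% at SNR 50) are optimistic relative to in-vivo values
(3–6%), and nothing here validates equivalence to any particular scanner
vendor's proprietary fitting. Reader jitter symmetrically swaps boundary
voxels, so delineations include some adjacent muscle whose shorter T
pulls stratum means a few percent below the configured tumor means —
most visibly where muscle and tumor differ most (T2 at either field) and
negligibly where they coincide (7 T T2\*). Problem sizes (64×64×3 maps, 15 subjects)
were chosen so the full study runs in well under a minute on one CPU;
results at larger matrices differ only in ROI sampling noise.

## Known limitations

* Mono-exponential model only; no multi-exponential, stretched
  exponential, or R2′ decomposition.
* ROIs live on the mapping grid; no resampling from a higher-resolution
  anatomic scan, no automatic segmentation.
* The CCC confidence interval is asymptotic; at n < 10 it is approximate.
* No DICOM/vendor-raw ingestion; NIfTI + JSON sidecar only.
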