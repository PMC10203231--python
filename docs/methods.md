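# Methods

This note records the models `cvrkit` implements, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
conventions — the package's own account of its science.

## Response kernels

**Canonical HRF.** Double-gamma difference with peak delay 6 s, undershoot
delay 16 s, unit dispersions and undershoot ratio 1/6, sampled on a fine
grid (dt = TR/16), support 32 s, peak-normalized to 1. This is the
conventional parameterization used by the major fMRI packages; its argmax
falls at 5.0 s.

**Respiratory response function (RRF).** The published difference-of-gammas
for respiratory/hypercapnic challenges,

    rrf(t) = 0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25),

peak-normalized, support 60 s. Its undershoot is far deeper than the HRF's
(|min|/|max| ≈ 1.11 vs 0.089) and far longer (still ≈ −39% of peak at 30 s,
recovering only after ~50 s), which is why the support must exceed the
32 s conventional for the HRF. Note the *time of the minimum* is nearly the
same for both kernels (~15.5 s); "longer, larger undershoot" is a statement
about depth and duration, not onset, and the shape tests assert exactly
that. The coefficients are exposed in `kernels.RRF_COEFFICIENTS` so
alternative parameterizations can be swapped in.

**Regressor construction.** Inputs (event sticks, breath-hold ramps,
end-tidal series) are built at dt = TR/16, discretely convolved with the
kernel, and sampled at volume onsets (slice-timing reference 0; the
synthetic data are generated already aligned, so no further timing
correction applies). A unit impulse reproduces the sampled kernel exactly.
The pre-sampling peak height of each regressor is retained for PSC scaling.

**Breath-hold ramp.** Within each hold epoch the input rises linearly 0→1
(arterial CO2 accumulating while breathing is suspended) and resets to 0 at
epoch end; washout dynamics are carried by the kernel's long undershoot. A
config flag (`extend_into_rest`) holds the terminal value instead, for the
alternative reading in which the stimulus persists into recovery.

## GLM engine

Mass-univariate OLS with a shared design per run: regressors of interest
plus nuisance (constant; linear drift by default, optional cosine high-pass
with 128 s cutoff; six mean-centred motion parameters). Fitting is by QR
factorization — the exact normal-equation solution, verified against
brute-force `(X'X)^{-1}X'y` to 1e-10 on random problems. Contrast t maps
use one-sided upper-tail p (activation contrasts are directional);
zero-variance voxels are masked with a logged count rather than raised,
since synthetic backgrounds are exactly constant.

**PSC convention.** The study design this package follows never states its
PSC formula, so one had to be fixed:

    psc = 100 · (w·β) · peak_height(w-weighted regressor) / β_constant,

i.e. the peak percent excursion of the fitted response relative to the
voxel baseline. This makes noiseless simulation round-trips exact and is
the convention of contrast-based PSC extraction in the SPM-family tooling.
A raw-beta-ratio variant is available (`scale_by_peak=False`).

**Smoothing.** None in breath-hold (exp1) mode; optional 4 mm FWHM Gaussian
pre-GLM filter in gas (exp2) mode, matching the two acquisition presets
(TR 2.0 s vs 1.8 s).

## Breath-hold CVR: staggered-onset selection

One GLM per onset lag in {0, TR, …, 12 s}; the selection statistic is the
count of voxels with one-sided p < 0.001 within the mask. On low-noise data
this count saturates at the mask size for every lag, so counts alone cannot
identify the delay; ties are therefore broken by the larger summed positive
t over the mask, and only then by the smaller lag (stability, avoids
drifting late). This keeps the "most significant voxels" selection rule
while making lag recovery exact on noiseless data — a property the
count-only rule cannot have.

**Kernel fallback.** If the best RRF model's significant-voxel count falls
below a threshold, the search is rerun with the canonical HRF and whichever
kernel yields more significant voxels wins (ties keep the RRF);
`fallback_used` is set only when the HRF is actually adopted. The default
threshold (100 voxels) is sized for whole-brain acquisitions; on small
phantoms, where the matched kernel saturates significance, the threshold is
set near the mask size so the decisive step is the count comparison. The
cohort experiment simulates 114 subjects of whom 15 carry HRF-shaped
breath-hold responses, at 2% noise — a level at which matched-kernel
per-voxel t sits in a realistic single-subject range — and identifies the
kernel correctly for every subject, reproducing a 13% fallback rate.

## Gas CVR

End-tidal extraction finds per-breath CO2 maxima (local peaks ≥ 2 s apart
with ≥ 2 mmHg prominence — the trace oscillates between inspired and
end-tidal levels at the ~4 s breathing period, so these settings isolate
one peak per breath) and interpolates them linearly onto volume times. The
baseline is the mean end-tidal value over pre-challenge breaths;
`max_change` is the excursion of the interpolated series above it.

The shift search delays the end-tidal series forward in TR steps (CO2
precedes the BOLD response) over 0–18 s, computing Pearson r on overlapping
samples only and taking the argmax of r (not |r|); smallest shift wins
ties. The shifted series enters the GLM in mmHg, so the contrast estimate
is interpretable per mmHg directly; the final map is nevertheless computed
as PSC ÷ max_change for fidelity to the standard route, and the two agree
by construction since the regressor's peak height equals the excursion.

## Synthetic data: what it emulates and what it does not

The phantom partitions a small grid into connected rectangular parcels
(default 68, mirroring a whole-cortex gyral parcellation; ≥ 20 voxels
each). Regional CVR is lognormal (median 0.2 %BOLD/mmHg, log-sd 0.4 —
positive and right-skewed as in real reactivity maps); each subject carries
a lognormal multiplicative vascular scale (log-sd 0.25) — without this
inter-subject spread the across-subject ROI regressions would have a
constant predictor. Task amplitudes follow
`b0 + b1·(cvr·ΔPetCO2) + N(0, 0.3)` with defaults b0 = 0.2 %, b1 = 0.5.
The breath-hold plateau PSC is scaled by a nominal end-tidal rise of
9.81 mmHg (the gas challenge's measured rise), putting breath-hold PSC near
2% — the range reported for strongly reactive cortex.

Forward models: breath-hold responses are ramp⊗RRF (or ramp⊗HRF for
"poor-RRF-fit" subjects), peak-normalized and scaled to `cvr·ΔPetCO2`; gas
responses convolve the ideal end-tidal excursion with a *unit-gain,
positive* hemodynamic kernel (the HRF's main gamma lobe). The positive
kernel is deliberate: a biphasic kernel's step response overshoots a
sustained plateau by ~14% through its undershoot lobe, which would break
the defining identity "plateau PSC = cvr·ΔPetCO2"; with the monotone kernel
the identity is exact. Event-task responses are correct-trial sticks⊗HRF
scaled to the coupled amplitude, with a 10% incorrect-trial fraction
carrying an independent amplitude (exercising the separate
regressor-of-no-interest path). The subject's hemodynamic lag (drawn from
the lag grid) delays the breath-hold and gas responses only: task GLMs here
and in practice use the canonical HRF with no lag search, so a 4–6 s
vascular delay injected into task responses would be unrecoverable by
construction; task timing variability is instead absorbed by the HRF
convention itself.

The capnograph trace oscillates sinusoidally (4 s period) between the
inspired floor and an end-tidal envelope with 15-s raised-cosine
transitions between the 35.38 mmHg baseline and the 45.19 mmHg hypercapnic
plateau, so per-breath maxima track the envelope exactly and the end-tidal
rise is 9.81 mmHg by construction.

Noise is white Gaussian, specified in percent of baseline (default 1%),
with optional AR(1) (coefficient 0.3 suggested). Not emulated: head motion
effects on the signal (motion parameters are emitted as pure nuisance),
slice timing, distortion, physiological noise structure, surface anatomy,
partial voluming. Passing tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to real
acquisition artefacts.

## ROI coupling

Per subject, task PSC and CVR maps are thresholded at one-sided p < 0.001
and averaged per parcel over jointly significant voxels only. Outlier
handling, in order: a single-pass mean-absolute-deviation filter (k = 3) on
the ROI's CVR values (a guard against large-vessel contamination), then a
single-pass per-coordinate 3-SD filter on the pairs. Both the mean-centred
and median-centred MAD conventions are implemented (`mad_center`), and the
summary records which ran; note the two genuinely disagree — in
{1,1,1,1,100} the mean-centred rule keeps the outlier (3·MAD = 95.04 >
79.2) while the median-centred rule removes it — and the wording "mean
absolute deviations" does not disambiguate which was intended, so the
default follows the literal reading (mean-centred). ROIs with fewer than 10
subjects after filtering are dropped (a sample-size floor below which
regression estimates are unstable); surviving ROIs get OLS of task PSC on
CVR with two-sided slope p, corrected by Benjamini–Hochberg step-up across
the ROI family of each task (per-task families, since each task's
regression set is a separate analysis; cross-task pooling is available via
config). The summary reports counts, the percentage significant to one
decimal, a top-k table and a polar-plot-ready R² export.

Voxel selection by significance inflates R² (only robustly activated
voxels enter) and this is inherent to the design; the property preserved —
and asserted in tests — is that selection cannot flip the sign of a true
positive coupling at high SNR.

## Group correction

Uncorrected: standard one-sample t across subject contrast images,
dof n−1. Voxel-wise correction: at each voxel, subject contrasts are
modelled on an intercept plus the mean-centred covariate image values at
that voxel; because the covariate is centred it is orthogonal to the
intercept, the intercept estimate remains the group mean, and the reported
statistic is the intercept t with dof n−2 — the group effect with
covariate-explained variance removed. Covariate-degenerate voxels fall
back to the uncorrected model and are counted. ROI-level correction is the
same model with one scalar covariate per subject inside ROI masks. Cluster
correction uses a sign-flip permutation null for maximum cluster extent
(default 1000 permutations, cluster-forming p = 0.005, familywise 0.05)
instead of external cluster-simulation tooling; a plain voxel-p mode
mirrors uncorrected p < 0.001 reporting.

## Validation experiments and problem sizes

The experiments module fixes the study conditions used by the test suite
and the acceptance script, sized so the full sweep runs in well under a
minute of CPU each: OLS-vs-oracle on 200 random ≤ 20×5 problems; lag
recovery on a 4-parcel 8×8×6 phantom (noiseless grid sweep plus 50
replicates at 1% noise); gas recovery on the full 68-parcel 24×24×18
phantom at 0.5% noise; the 114-subject fallback cohort at 2% noise;
coupling recovery at the parcel level (200 replicates × 100 subjects,
slope 0.5, subject sd 0.3 — the imaging round-trip being validated
separately, the ROI samples are formed directly from the truth); 500
null-coupling replicates for FDR control; and 100 replicates of the
covariate-correction contrast. Typical outcomes: recovery slope ≈ 0.996
with R² > 0.999; CI coverage ≈ 94.7%; null significant fraction ≈ 0.002;
correction win rate 100%.

## Known limitations

* The estimators are validated on phantoms whose generative model matches
  the analysis assumptions; real-data deviations (nonlinear CVR at high
  CO2, sigmoidal saturation, motion-correlated signal, vascular steal) are
  out of scope.
* The shift/lag searches are grid searches at TR resolution; sub-TR delays
  bias amplitude estimates slightly (visible as the ~0.4% slope shortfall
  in gas recovery).
* The MAD/SD outlier filters are single-pass by design; iterated filtering
  would change the retained sets.
* ROI hemisphere labels on the phantom come from the grid's x-split and
  are metadata for the polar export, not anatomy.
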