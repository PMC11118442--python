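# Methods

This note documents the models, conventions and design choices behind
`microdyn`, in the spirit of the methods documentation of mature analysis
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic benchmarks do and do not establish.

## Preprocessing

The chain is notch (49.8–50.2 Hz band-stop), 5th-order Butterworth high-pass
at 0.3 Hz and low-pass at 70 Hz, polyphase FIR downsampling to 250 Hz,
average re-referencing, and a 180 s analysis segment taken from offset 0 by
default. All IIR filters run forward–backward (`sosfiltfilt`), i.e.
zero-phase: microstate analysis labels individual frames, so group delay
would systematically shift topography timing. The notch is realized as a
2nd-order Butterworth band-stop (4 poles): with a 0.4 Hz stop band a higher
order buys nothing and lengthens the ring-down. The high/low-pass orders
follow the published analysis recipe. Filtering requires fs > 140 Hz so the
70 Hz cutoff stays below Nyquist.

Component-based (ICA) artifact rejection requires visual curation and is not
reproducible from a written recipe; `remove_artifacts` is therefore a
pass-through hook where externally cleaned data enter the pipeline. The
choice of which 180 s to analyze is likewise a data-quality judgement; the
default (the first 180 s) is a convention, not a claim.

## Synthetic data generator

The generator emulates exactly the assumptions microstate analysis makes:

* K = 4 fixed template maps over 19 channels, average-referenced, unit GFP,
  mutually orthogonal in the zero-mean channel subspace (so spatial
  correlations between classes are zero — cleaner than real maps, which
  correlate at 0.3–0.5);
* piecewise-constant activation: a semi-Markov chain whose state durations
  are gamma(shape 4) with mean 80 ms by default. Gamma rather than
  exponential because empirical microstate durations are unimodal and
  bounded away from zero, which is also the regime the 30 ms smoothing rule
  presupposes;
* a transition matrix interpolated between a deterministic cycle
  (`structure = 1`) and uniform off-diagonal transitions (`structure = 0`) —
  the single knob that makes transition *ordering* informative while leaving
  the symbol distribution unchanged;
* slow sinusoidal amplitude modulation (0.3 Hz, ±40 %) standing in for GFP
  waxing and waning;
* additive 1/f^α noise (α = 1 by default), spatially white then
  re-referenced, scaled to a global signal/noise RMS ratio (`snr`, default
  3).

Cohorts share one template set; groups differ only in the distribution of
the structure parameter (HC-like 0.70–0.90, FTD-like 0.35–0.55, AD-like
0.05–0.25), and each subject's cognitive score is a stated linear function
of that parameter plus Gaussian noise (defaults: 18 + 14·structure, σ = 1,
giving an MMSE-like 18–31 range across groups).

What passing synthetic benchmarks does **not** show: robustness to
correlated template maps, artifacts, non-stationary noise, inter-subject
topographic variability, or violations of the piecewise-constant model.
They validate the estimators under the model's own assumptions, not the
biology.

## EMD and CEEMD

EMD sifts each series with cubic-spline envelopes through the local extrema,
mirroring two extrema beyond each boundary to control spline end effects.
Sifting stops when the normalized squared envelope-mean energy falls below
0.2 (Cauchy-type criterion), capped at 50 sift iterations per mode for
determinism; mode extraction stops when the residue has fewer than three
extrema. Sums of modes plus residue reproduce the input to float rounding by
construction.

CEEMD decomposes `x + N_i` and `x − N_i` for each of 100 white-noise
realizations (σ = 0.1 relative to the channel SD — the amplitude is read as
*relative* because an absolute 0.1 µV would vanish against µV-scale EEG) and
averages IMFs index-wise, padding shorter decompositions with zero modes.
Because the noise enters in complementary pairs, the averaged decomposition
sums exactly to the source for any ensemble size. Channels are decomposed
independently with sub-seeds spawned from one seed, and mode counts are
harmonized across channels by zero-padding so that "IMF2" means the same
index everywhere. The frequency ordering of modes (spectral centroid
non-increasing with index) holds for oscillatory modes; near-residue trend
modes with centroids below the 0.3 Hz analysis band carry negligible energy
and their centroids are estimation noise, so ordering checks exclude them.

Ensemble-size accounting: "100 iterations" is implemented as 100
complementary *pairs* (200 decompositions).

## Microstate segmentation

Clustering operates on topographies at GFP peaks (local maxima ≥ 10 ms
apart; peaks above mean + 1 SD of the GFP series are excluded as likely
artifactual; if more than 2000 survive, a uniformly spaced subsample of
exactly 2000 is kept — exclusion happens before capping). The modified
K-means ignores polarity: frames are assigned by squared spatial
correlation, and each template is re-estimated as the first principal
direction of its members (sign fixed by making the largest-magnitude
component positive). A restart converges when the relative change in
residual noise variance drops below 10⁻⁶; the best of 50 restarts by global
explained variance (GEV = Σ(GFP·corr)² / ΣGFP²) wins. Empty clusters are
re-seeded with the worst-fit map. All ties break to the lowest class index.

Backfitting is winner-takes-all on |spatial correlation| with rejection
below 0.5 (such frames stay unlabeled). Runs shorter than 30 ms are
reassigned frame-wise to the non-current class with smallest global map
dissimilarity (GMD); for unit-GFP maps GMD = √(2 − 2|corr|), so the ordering
comes directly from the correlation matrix. The passes carry a cycle guard:
when every run is short, the frame-wise rule forces true-class frames off
their class and the labeling can oscillate. Any short run remaining after
the passes is absorbed into the contiguous neighboring run whose class has
the smaller mean GMD over the run's frames (shortest run first; each merge
reduces the run count, so this terminates). Runs isolated between unlabeled
gaps have no contiguous neighbor and are left. Unlabeled frames are never
modified and split runs for all run-based statistics.

A 20 ms smoothing window is sometimes quoted for this class of analysis;
30 ms is the default here (`smooth_min_duration_ms` is configurable).

Duration is the mean run length per class in ms (undefined, reported as NaN,
for a class that never occurs); occurrence is runs per second of *labeled*
time; coverage is the fraction of labeled frames. Unlabeled frames are
excluded from all denominators.

## IBS distance, MSNRI, MSLZC

The transition sequence drops unlabeled frames and collapses consecutive
duplicates. The IBS distance between two sequences at word length m uses
these conventions, fixed for determinism:

* vocabulary = union of the m-words observed in either sequence (size K);
  the classical 2^m count presupposes a binary alphabet and is replaced by
  K, with normalization K − 1, keeping D ∈ [0, 1];
* within each sequence, ranks are assigned by descending probability,
  ties broken lexicographically; words absent from a sequence take p = 0
  (with 0·log 0 = 0) and rank after all present words, lexicographically
  among themselves;
* entropy weights use the natural log (the base cancels through the
  normalization Z); if Z = 0 (each sequence concentrated on a single word)
  weights fall back to uniform.

MSNRI is the mean IBS distance between a sequence and 20 uniform-shuffle
surrogates (re-collapsed after shuffling so they remain valid transition
sequences), reported ×100; `n_surrogates=1` reproduces the literal
single-shuffle definition, 20 reduces surrogate variance. The headline word
length is m = 8, with m = 4..8 used as features.

**Sampling caveat.** The union-vocabulary rank statistic needs the number of
windows (≈ sequence length) to be large relative to the possible vocabulary
(4·3^(m−1) for four no-repeat symbols). A 180 s recording yields ≈ 2200
transitions; at m = 8 the 8748-word space is undersampled, most observed
words are singletons, and the distance becomes dominated by vocabulary
disjointness between a sequence and its shuffle — which *reverses* the
intuitive ordering (a random sequence then sits *farther* from its shuffles
than a periodic one). At m ≤ 6 the ordering is monotone in transition
structure. Consequently the package's ordering benchmarks (periodic vs
random, structured vs uniform groups) run at m = 4, the well-sampled end of
the feature range; m = 8 features remain available and are still
discriminative as inputs to a regression, but their sign should not be
interpreted in isolation at this sequence length.

MSLZC is the LZ76 exhaustive-history phrase count divided by the sequence
length. LZ76 is used because it is the well-defined, implementation-
independent variant of dictionary complexity (compressor-specific dictionary
sizes are not portable). It is computed on the collapsed transition
sequence. Time-series variants (for raw EEG channels) binarize by increment
coding — symbol 1 where the series rises — without duplicate collapsing;
this coding is a convention, chosen for its simplicity and invariance to
monotone amplitude transforms.

## Statistics and prediction

Group contrasts use the Mann–Whitney U test in its normal approximation with
tie-corrected variance and continuity correction, reporting z (positive when
the first sample tends larger) and two-sided p. The approximation matches
exhaustive enumeration to ≈ 0.01–0.03 at n per group ≤ 8 (worst in the
extreme tail) and tightens rapidly with n; for the cohort sizes this package
targets (≥ 20) it is accurate to well below 0.01.

Feature tables contain, per scale (broadband, IMF2–IMF5): MSNRI at
m = 4..8, MSLZC, and per-class duration/occurrence/coverage — 18 columns per
scale, 90 for the five-scale variant. The baseline variant uses broadband
only.

LOSO prediction fits ordinary least squares per fold after min–max scaling
each feature on the training fold only; the held-out subject's scaled values
are clipped to [0, 1]. Scaling inside the fold costs a little apparent
accuracy versus global scaling but avoids information leakage. Rank-deficient
designs (more features than training subjects, possible for the five-scale
variant on small cohorts) are resolved by minimum-norm least squares with a
warning. R², MSE, RMSE and MAE are computed on the pooled held-out
predictions — one number across folds, matching how predicted-vs-observed
scatter plots are drawn. With zero score noise, pooled R² is slightly below
1 (≈ 0.999) purely because held-out subjects at the edge of the feature
range are clipped.

## Pipeline

`run_pipeline` wires the stages together from a manifest (subject files,
group, score) and a config whose defaults are the published analysis values
(180 s, 250 Hz, K = 4, 2000 peaks, 10 ms peak spacing, 30 ms smoothing, 0.5
rejection, CEEMD 0.1/100, m = 8 headline, 20 surrogates). Per-stage seeds
are spawned deterministically from one master seed; per-subject label
sequences are cached on disk keyed by a hash of the full config, so reruns
are bit-identical and any parameter change invalidates the cache. The report
contains per-scale group summaries (mean ± SD and pairwise rank-sum z/p for
MSNRI and MSLZC) and LOSO metrics for baseline/five-scale variants on the
full cohort and the disease-only subset.

## Benchmark problem sizes

The packaged benchmarks use sizes chosen to exercise the full method while
remaining desk-scale: CEEMD reconstruction on one 19 × 45 000 recording with
a single complementary pair (the completeness identity is
ensemble-size-independent); template/label recovery on 60 s at snr 3; the
MSNRI group contrast on 20 + 20 label sequences of 180 s generated directly
from the semi-Markov model (the index is a property of the sequence, so
clustering is exercised separately); LOSO recovery on 30 subjects. Group
templates in the pipeline are clustered from pooled GFP-peak maps across
subjects, mirroring the all-participants template strategy.

## Known limitations

* EMD has no variational characterization; results depend on the stated
  sifting conventions (envelope spline, boundary mirroring, stop criterion).
  Different conventions yield slightly different mode splits.
* The MSNRI m = 8 undersampling caveat above.
* The smoothing finalization (neighbor absorption) is a deterministic
  repair for pathological fragmentations; real backfit label noise is
  handled by the standard GMD passes.
* Unlabeled frames split runs; bridging them is a defensible alternative
  that would lengthen durations slightly.
* The generator does not model correlated templates, artifacts, or
  inter-subject map variability (see the synthetic-data section).
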